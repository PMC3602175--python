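"""Published summary data for the 35 newly sequenced chlorovirus isolates.

These are the printed per-genome features (host group, contig count, genome
size, %GC, gene counts and GenBank accession) of the 35 draft chlorovirus
genomes, used as inputs for summary statistics and as expected values for
the full-scale benchmarks.  Sequences themselves are not bundled; they can
be fetched from GenBank (accessions JX997153-JX997187) for full-scale runs.
"""

from __future__ import annotations

import io

import pandas as pd

_GENOME_TABLE_TSV = """\
virus\thost_group\tn_contigs\tgenome_size_kb\tcoverage\tpct_gc\tn_protein_genes\tn_trna_genes\tn_protein_families\taccession
AN69C\tNC64A\t8\t332\t29\t40\t362\t10\t278\tJX997153
CviKI\tNC64A\t8\t308\t55\t40\t336\t14\t271\tJX997162
CvsA1\tNC64A\t9\t310\t36\t40\t342\t14\t272\tJX997165
IL-3A\tNC64A\t3\t323\t50\t40\t349\t12\t273\tJX997169
IL-5-2s1\tNC64A\t9\t344\t65\t41\t379\t8\t281\tJX997170
KS1B\tNC64A\t7\t287\t46\t40\t319\t13\t257\tJX997171
MA-1D\tNC64A\t9\t339\t45\t41\t371\t11\t288\tJX997172
MA-1E\tNC64A\t39\t336\t27\t40\t376\t14\t269\tJX997173
NE-JV-4\tNC64A\t8\t328\t41\t40\t352\t11\t276\tJX997179
NY-2B\tNC64A\t5\t344\t59\t41\t371\t8\t281\tJX997182
NYs-1\tNC64A\t9\t348\t64\t41\t381\t7\t286\tJX997183
AP110A\tPbi\t6\t327\t27\t44\t348\t9\t269\tJX997154
Can18-4\tPbi\t11\t329\t52\t45\t357\t10\t271\tJX997157
CVA-1\tPbi\t8\t326\t36\t45\t346\t9\t270\tJX997159
CVB-1\tPbi\t8\t319\t90\t44\t346\t10\t272\tJX997160
CVG-1\tPbi\t7\t318\t48\t45\t333\t9\t262\tJX997161
CVM-1\tPbi\t5\t327\t48\t44\t341\t9\t268\tJX997163
CVR-1\tPbi\t11\t329\t39\t45\t351\t9\t268\tJX997164
CZ-2\tPbi\t11\t305\t39\t45\t340\t10\t262\tJX997166
Fr5L\tPbi\t22\t302\t58\t45\t345\t11\t257\tJX997167
NE-JV-1\tPbi\t8\t326\t45\t47\t337\t3\t265\tJX997176
NW665.2\tPbi\t6\t325\t62\t44\t350\t8\t263\tJX997181
OR0704.2.2\tPbi\t8\t313\t53\t45\t344\t7\t261\tJX997184
Br0604L\tSAG\t2\t295\t65\t49\t346\t9\t272\tJX997155
Can0610SP\tSAG\t1\t307\t61\t49\t341\t13\t267\tJX997156
Canal-1\tSAG\t4\t293\t50\t51\t336\t10\t277\tJX997158
GM0701.1\tSAG\t4\t315\t71\t48\t362\t10\t272\tJX997168
MN0810.1\tSAG\t6\t327\t57\t52\t343\t9\t268\tJX997174
MO0605SPH\tSAG\t3\t289\t107\t49\t323\t11\t271\tJX997175
NE-JV-2\tSAG\t4\t319\t40\t48\t346\t13\t271\tJX997177
NE-JV-3\tSAG\t3\t298\t63\t49\t334\t12\t268\tJX997178
NTS-1\tSAG\t4\t323\t35\t48\t364\t7\t271\tJX997180
OR0704.3\tSAG\t5\t311\t49\t49\t342\t13\t272\tJX997185
TN603.4.2\tSAG\t3\t321\t28\t49\t351\t9\t276\tJX997186
WI0606\tSAG\t7\t289\t58\t50\t329\t11\t271\tJX997187
"""


def reference_genome_table() -> pd.DataFrame:
    """Per-isolate features of the 35 newly sequenced chlorovirus genomes."""
    return pd.read_csv(io.StringIO(_GENOME_TABLE_TSV), sep="\t")
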