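"""Compositional deviation index (CDI) for detecting recently acquired genes.

A genome's vertically inherited ("ancestral") coding sequences are summarised
by a non-homogeneous Markov chain of order ``k`` (default 5) over nucleotides:
an initial distribution ``P0`` over the first k-tuple of an ORF, and three
transition matrices ``P1, P2, P3`` giving the probability of the next
nucleotide conditioned on the preceding k-tuple, where the matrix used
depends on the codon position (1, 2 or 3) of the k-tuple's first nucleotide.
Because coding constraints differ by codon position, conditioning the chain
on reading-frame phase captures the periodic structure of coding DNA.

Each ORF is scored by its log-likelihood under the model of its own genome,
standardised against ``n_rand`` (default 100) random coding sequences of the
same length emitted from the model:

    CDI = (logP(ORF) - mean logP(random)) / SD(logP(random))

ORFs whose composition matches the ancestral model score near 0; ORFs with
deviant composition - the signature expected of recent horizontal transfers
from compositionally distinct donors - score far from 0, typically in the
negative tail.  All likelihood arithmetic is carried out in log space: raw
products of per-nucleotide probabilities underflow for any realistic ORF
length, and standardising log-likelihoods preserves the "expected CDI = 0"
calibration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_CODE_NT = np.array(list("ACGT"))


class TrainingError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 (A,C,G,T -> 0..3; ambiguity -> -1)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for nt, code in _NT_CODE.items():
        out[arr == ord(nt)] = code
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(_CODE_NT[codes])


def _tuple_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer code of every k-tuple (first nucleotide most significant).

    Returns (tuple_codes, valid_mask); windows containing an ambiguity code
    are masked out.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = (windows.astype(np.int64) * powers).sum(axis=1)
    return vals, valid


@dataclass
class CodonMarkovModel:
    """Order-k codon-position-specific Markov model of coding sequence.

    ``p0`` has shape (4^k,); ``trans`` has shape (3, 4^k, 4) indexed by the
    codon position (0-based frame index) of the context tuple's first
    nucleotide.  ``n0`` and ``n_trans`` keep the raw training counts.
    """

    k: int
    p0: np.ndarray
    trans: np.ndarray
    alpha: float = 0.5
    n0: np.ndarray | None = None
    n_trans: np.ndarray | None = None
    training_set_id: str = ""

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("model order k must be >= 1")
        self.log_p0 = np.log(self.p0)
        self.log_trans = np.log(self.trans)

    @property
    def n_contexts(self) -> int:
        return 4 ** self.k

    # -- serialisation ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "schema": "chlorocomp-codon-markov-model/1",
            "k": self.k,
            "alpha": self.alpha,
            "training_set_id": self.training_set_id,
            "p0": self.p0.tolist(),
            "trans": self.trans.tolist(),
            "n0": None if self.n0 is None else self.n0.tolist(),
            "n_trans": None if self.n_trans is None else self.n_trans.tolist(),
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "CodonMarkovModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            k=obj["k"],
            p0=np.asarray(obj["p0"]),
            trans=np.asarray(obj["trans"]),
            alpha=obj["alpha"],
            n0=None if obj["n0"] is None else np.asarray(obj["n0"]),
            n_trans=None if obj["n_trans"] is None else np.asarray(obj["n_trans"]),
            training_set_id=obj.get("training_set_id", ""),
        )


@dataclass(frozen=True)
class CDIResult:
    orf_id: str
    length_nt: int
    log_likelihood: float
    null_mean: float
    null_sd: float
    cdi: float | None
    n_rand: int
    flag: str = ""  # "", "undefined_sd", "too_short"


def train_model(ancestral_orfs: Iterable[str], k: int = 5, alpha: float = 0.5,
                training_set_id: str = "") -> CodonMarkovModel:
    """Fit the codon-position Markov model to a set of in-frame coding sequences.

    ``p0`` is the pseudocounted frequency of each ORF's first k-tuple;
    transitions are ``(N(j,i,f) + alpha) / (N(j,f) + 4 alpha)`` where ``f``
    is the codon position of context ``j``'s first nucleotide.  Tuples
    containing ambiguity codes are skipped.  ORFs are trimmed to a whole
    number of codons.
    """
    if k < 1:
        raise ValueError("model order k must be >= 1")
    nctx = 4 ** k
    n0 = np.zeros(nctx, dtype=np.int64)
    n_trans = np.zeros((3, nctx, 4), dtype=np.int64)
    total_nt = 0
    n_orfs = 0
    for orf in ancestral_orfs:
        codes = encode(orf)
        codes = codes[: len(codes) - len(codes) % 3]
        if len(codes) < k + 1:
            continue
        n_orfs += 1
        total_nt += len(codes)
        tuples, valid = _tuple_codes(codes, k)
        if valid[0]:
            n0[tuples[0]] += 1
        # transition at emitted position t = s + k; context starts at s,
        # codon position of s is s % 3
        s_idx = np.arange(len(tuples) - 1)
        nxt = codes[k:]
        ok = valid[:-1] & (nxt >= 0)
        frames = s_idx % 3
        np.add.at(n_trans, (frames[ok], tuples[:-1][ok], nxt[ok].astype(np.int64)), 1)
    if n_orfs == 0:
        raise TrainingError("empty training set")
    if total_nt < 10 * 4 ** (k + 1):
        warnings.warn(
            f"training set has {total_nt} nt; fewer than the recommended "
            f"{10 * 4 ** (k + 1)} for order k={k}")
    p0 = (n0 + alpha) / (n0.sum() + alpha * nctx)
    row_tot = n_trans.sum(axis=2, keepdims=True)
    trans = (n_trans + alpha) / (row_tot + 4 * alpha)
    return CodonMarkovModel(k=k, p0=p0, trans=trans, alpha=alpha,
                            n0=n0, n_trans=n_trans,
                            training_set_id=training_set_id)


def orf_log_likelihood(orf: str | np.ndarray, model: CodonMarkovModel,
                       ) -> float | None:
    """Log-likelihood of an ORF under the model.

    The ORF is assumed to start at codon position 1.  Positions whose
    context window or emitted nucleotide carries an ambiguity code
    contribute 0 to the log-sum.  Returns None when fewer than k+1 usable
    nucleotides are available.
    """
    codes = encode(orf) if isinstance(orf, str) else orf
    k = model.k
    if len(codes) < k + 1:
        return None
    tuples, valid = _tuple_codes(codes, k)
    logp = model.log_p0[tuples[0]] if valid[0] else 0.0
    s_idx = np.arange(len(tuples) - 1)
    nxt = codes[k:]
    ok = valid[:-1] & (nxt >= 0)
    frames = s_idx % 3
    logp += model.log_trans[frames[ok], tuples[:-1][ok], nxt[ok].astype(np.int64)].sum()
    return float(logp)


def log_likelihood_batch(seqs: np.ndarray, model: CodonMarkovModel) -> np.ndarray:
    """Vectorised log-likelihood for an (n, L) int matrix of unambiguous sequences."""
    n, L = seqs.shape
    k = model.k
    if L < k + 1:
        raise ValueError("sequences shorter than k+1")
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(seqs, k, axis=1)
    tuples = (windows.astype(np.int64) * powers).sum(axis=2)  # (n, L-k+1)
    out = model.log_p0[tuples[:, 0]].copy()
    s_idx = np.arange(L - k)
    frames = s_idx % 3
    nxt = seqs[:, k:].astype(np.int64)
    out += model.log_trans[frames[None, :], tuples[:, :-1], nxt].sum(axis=1)
    return out


def _decode_context(ctx: np.ndarray, k: int) -> np.ndarray:
    """(n,) context codes -> (n, k) nucleotide codes."""
    out = np.empty((len(ctx), k), dtype=np.int8)
    rem = ctx.copy()
    for pos in range(k - 1, -1, -1):
        out[:, pos] = rem % 4
        rem //= 4
    return out


def sample_orf_batch(model: CodonMarkovModel, length_nt: int, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Emit ``n`` random coding sequences of ``length_nt`` nt from the model."""
    k = model.k
    if length_nt < k + 1:
        raise ValueError(f"length must be >= k+1 = {k + 1}")
    seqs = np.empty((n, length_nt), dtype=np.int8)
    ctx = rng.choice(model.n_contexts, size=n, p=model.p0)
    seqs[:, :k] = _decode_context(ctx, k)
    mod = 4 ** (k - 1)
    u = rng.random((n, length_nt - k))
    for s in range(length_nt - k):
        rows = model.trans[s % 3, ctx]           # (n, 4)
        cdf = np.cumsum(rows, axis=1)
        nxt = (u[:, s, None] < cdf).argmax(axis=1)
        seqs[:, k + s] = nxt
        ctx = (ctx % mod) * 4 + nxt
    return seqs


def sample_orf(model: CodonMarkovModel, length_nt: int,
               seed: int | np.random.Generator) -> str:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return decode(sample_orf_batch(model, length_nt, 1, rng)[0])


def compute_cdi(orf: str, model: CodonMarkovModel, n_rand: int = 100,
                seed: int | np.random.Generator = 0,
                orf_id: str = "") -> CDIResult:
    """CDI of one ORF against ``n_rand`` model-emitted sequences of equal length."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = encode(orf)
    logp = orf_log_likelihood(codes, model)
    if logp is None:
        return CDIResult(orf_id, len(codes), float("nan"), float("nan"),
                         float("nan"), None, n_rand, flag="too_short")
    nulls = log_likelihood_batch(
        sample_orf_batch(model, len(codes), n_rand, rng), model)
    mu, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    # identical null draws can leave a rounding-level residue instead of 0
    if sd <= 1e-9 * max(1.0, abs(mu)):
        return CDIResult(orf_id, len(codes), logp, mu, sd, None, n_rand,
                         flag="undefined_sd")
    return CDIResult(orf_id, len(codes), logp, mu, sd, (logp - mu) / sd, n_rand)


def score_orfs(orfs: dict[str, str], model: CodonMarkovModel, n_rand: int = 100,
               seed: int = 0) -> pd.DataFrame:
    """CDI for a set of ORFs; one row per ORF.

    ORFs of equal length share a vectorised sampling path but each ORF gets
    its own ``n_rand`` null draws.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for orf_id, seq in orfs.items():
        res = compute_cdi(seq, model, n_rand=n_rand, seed=rng, orf_id=orf_id)
        rows.append({
            "orf_id": res.orf_id, "length_nt": res.length_nt,
            "logL": res.log_likelihood, "null_mean": res.null_mean,
            "null_sd": res.null_sd, "cdi": np.nan if res.cdi is None else res.cdi,
            "flag": res.flag,
        })
    return pd.DataFrame(rows)


def detection_auroc(cdi_values: Sequence[float],
                    is_alien: Sequence[bool]) -> float:
    """AUROC for ranking alien ORFs by CDI (lower CDI = more alien-like).

    Computed from the Mann-Whitney U statistic; ties share credit.
    """
    cdi_arr = np.asarray(cdi_values, dtype=float)
    alien = np.asarray(is_alien, dtype=bool)
    pos, neg = cdi_arr[alien], cdi_arr[~alien]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both alien and non-alien ORFs")
    u = stats.mannwhitneyu(-pos, -neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# Group comparison statistics
# ---------------------------------------------------------------------------

def cdi_group_comparison(cdi_values: Sequence[float], labels: Sequence[str],
                         length_nt: Sequence[int] | None = None,
                         orfan_flags: Sequence[bool] | None = None,
                         long_threshold_bp: int = 300) -> dict:
    """Omnibus and pairwise rank tests of CDI across ORF categories.

    Runs a Kruskal-Wallis omnibus over categories with >= 2 observations,
    then all pairwise two-sided Mann-Whitney tests with Holm family-wise
    correction.  When ``length_nt`` and ``orfan_flags`` are given, a named
    contrast compares long (> ``long_threshold_bp``) vs short ORFan genes.
    """
    df = pd.DataFrame({"cdi": np.asarray(cdi_values, dtype=float),
                       "label": list(labels)}).dropna(subset=["cdi"])
    groups = {}
    for label, sub in df.groupby("label"):
        if len(sub) < 2:
            warnings.warn(f"category {label!r} has <2 observations; excluded")
            continue
        groups[label] = sub["cdi"].to_numpy()
    if len(groups) < 2:
        raise ValueError("need >=2 categories with >=2 observations each")
    names = sorted(groups)
    kw_stat, kw_p = stats.kruskal(*[groups[g] for g in names])
    pair_rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            stat, p = stats.mannwhitneyu(groups[names[i]], groups[names[j]],
                                         alternative="two-sided")
            pair_rows.append({"group_a": names[i], "group_b": names[j],
                              "U": float(stat), "p_raw": float(p)})
    pairs = pd.DataFrame(pair_rows)
    if not pairs.empty:
        # Holm step-down family-wise correction
        order = np.argsort(pairs["p_raw"].to_numpy())
        m = len(pairs)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pairs["p_raw"].iloc[idx])
            adj[idx] = min(1.0, running)
        pairs["p_holm"] = adj
    out = {"kruskal_statistic": float(kw_stat), "kruskal_p": float(kw_p),
           "pairwise": pairs, "n_per_group": {g: len(v) for g, v in groups.items()}}
    if length_nt is not None and orfan_flags is not None:
        full = pd.DataFrame({
            "cdi": np.asarray(cdi_values, dtype=float),
            "length": np.asarray(length_nt),
            "orfan": np.asarray(orfan_flags, dtype=bool),
        }).dropna(subset=["cdi"])
        orfans = full[full["orfan"]]
        long_v = orfans.loc[orfans["length"] > long_threshold_bp, "cdi"].to_numpy()
        short_v = orfans.loc[orfans["length"] <= long_threshold_bp, "cdi"].to_numpy()
        if len(long_v) >= 2 and len(short_v) >= 2:
            stat, p = stats.mannwhitneyu(long_v, short_v, alternative="two-sided")
            out["orfan_long_vs_short"] = {"U": float(stat), "p": float(p),
                                          "n_long": len(long_v),
                                          "n_short": len(short_v)}
        else:
            out["orfan_long_vs_short"] = None
    return out
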