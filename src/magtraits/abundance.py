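"""Consortium-level computations: relative abundance, sketch ANI, re-occurrence.

Relative abundance: per-sample fractions of reads mapped to each genome,
summarized as mean +/- sd (sample sd, ddof=1) across samples.

ANI: a MinHash bottom-sketch estimator over canonical (strand-collapsed)
k-mers.  With Jaccard similarity j between the two sketch sets, the k-mer
survival probability is w = 2j/(1+j) and the identity estimate is
ANI = 100 * w**(1/k) — the exact form of the Mash-distance relation, which
agrees with the first-order expansion 100*(1 + ln(w)/k) near 100% identity
but stays unbiased down to 90%.  The estimator is a desk-scale stand-in for
whole-genome ANI tools; :func:`find_reoccurring` also accepts a precomputed
identity matrix so external ANI output can be dropped in.

Re-occurrence: a genome re-occurs in a second data set when its best match
there exceeds 97.5% identity (strict inequality, configurable), with
one-to-one matching enforced by greedy descending-ANI assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "relative_abundance",
    "read_counts",
    "estimate_ani",
    "ANIMatch",
    "find_reoccurring",
    "ani_matrix",
]

REOCCURRENCE_THRESHOLD = 97.5

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def read_counts(path) -> pd.DataFrame:
    """Read a sample x genome read-count TSV (first column = sample id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def relative_abundance(counts: pd.DataFrame) -> "tuple[pd.DataFrame, pd.DataFrame]":
    """Per-sample genome fractions plus cross-sample mean and sd per genome.

    ``counts`` is samples x genomes.  Fractions sum to 1 per sample; a
    zero-total sample is an error naming the sample.  Scale-invariant:
    multiplying one sample's counts by c > 0 changes nothing.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    totals = counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total counts")
    fractions = counts.div(totals, axis=0)
    summary = pd.DataFrame(
        {
            "mean_fraction": fractions.mean(axis=0),
            "sd_fraction": fractions.std(axis=0, ddof=1).fillna(0.0),
        }
    ).rename_axis("genome_id")
    return fractions, summary


# ---------------------------------------------------------------------------
# MinHash sketch ANI


def _splitmix64(x: np.ndarray) -> np.ndarray:
    x = x + np.uint64(0x9E3779B97F4A7C15)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def _sketch(seq: str, k: int, sketch_size: int, seed: int) -> np.ndarray:
    """Bottom-sketch of hashed canonical k-mers (sorted ascending)."""
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size < k:
        raise ValueError(f"sequence shorter than k ({arr.size} < {k})")
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (windows < 4).all(axis=1)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = (windows.astype(np.uint64) * powers).sum(axis=1)
    rc = (((np.uint64(3) - windows.astype(np.uint64))[:, ::-1]) * powers).sum(axis=1)
    canon = np.minimum(fwd, rc)[valid]
    salt = _splitmix64(np.array([seed], dtype=np.uint64))[0]
    hashes = np.unique(_splitmix64(canon ^ salt))
    return hashes[:sketch_size]


def estimate_ani(
    seq_a: str,
    seq_b: str,
    k: int = 16,
    sketch_size: int = 5000,
    seed: int = 0,
) -> float:
    """Estimate average nucleotide identity (%) between two sequences.

    Deterministic given ``seed``, symmetric in its arguments, and 100.0 for
    identical sequences.  Requires k in [11, 31] and sequences of length
    >= 10*k (shorter sequences make the sketch meaningless).
    """
    if not 11 <= k <= 31:
        raise ValueError(f"k must be in [11, 31] (got {k})")
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if len(seq) < 10 * k:
            raise ValueError(f"{name} shorter than 10*k ({len(seq)} < {10 * k})")
    ha = _sketch(seq_a, k, sketch_size, seed)
    hb = _sketch(seq_b, k, sketch_size, seed)
    union = np.union1d(ha, hb)[:sketch_size]
    shared = np.intersect1d(ha, hb, assume_unique=True)
    j = np.isin(union, shared, assume_unique=True).sum() / union.size
    if j <= 0.0:
        return 0.0
    w = 2.0 * j / (1.0 + j)
    return float(min(100.0, 100.0 * w ** (1.0 / k)))


# ---------------------------------------------------------------------------
# Re-occurrence matching


@dataclass(frozen=True)
class ANIMatch:
    genome_a: str
    genome_b: str
    ani_pct: float
    reoccurring: bool
    tie_flag: bool = False

    def as_row(self) -> dict:
        return {
            "genome_a": self.genome_a,
            "genome_b": self.genome_b,
            "ani_pct": f"{self.ani_pct:.3f}",
            "reoccurring": self.reoccurring,
            "tie_flag": self.tie_flag,
        }


def ani_matrix(
    seqs_a: Mapping[str, str],
    seqs_b: Mapping[str, str],
    k: int = 16,
    sketch_size: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """All-vs-all sketch ANI between two genome collections (rows = set A)."""
    sk_a = {n: _sketch(s, k, sketch_size, seed) for n, s in seqs_a.items()}
    sk_b = {n: _sketch(s, k, sketch_size, seed) for n, s in seqs_b.items()}
    out = pd.DataFrame(index=list(seqs_a), columns=list(seqs_b), dtype=float)
    for na, ha in sk_a.items():
        for nb, hb in sk_b.items():
            union = np.union1d(ha, hb)[:sketch_size]
            shared = np.intersect1d(ha, hb, assume_unique=True)
            j = np.isin(union, shared, assume_unique=True).sum() / union.size
            if j <= 0.0:
                out.loc[na, nb] = 0.0
            else:
                w = 2.0 * j / (1.0 + j)
                out.loc[na, nb] = min(100.0, 100.0 * w ** (1.0 / k))
    return out


def find_reoccurring(
    seqs_a: Optional[Mapping[str, str]] = None,
    seqs_b: Optional[Mapping[str, str]] = None,
    threshold: float = REOCCURRENCE_THRESHOLD,
    k: int = 16,
    sketch_size: int = 5000,
    seed: int = 0,
    identity: Optional[pd.DataFrame] = None,
) -> "list[ANIMatch]":
    """Best-hit, one-to-one matching of set A genomes against set B.

    Pairs are assigned greedily in descending ANI order so no genome is used
    twice; exact ties on ANI are flagged.  ``reoccurring`` is strict:
    ani > threshold.  A precomputed identity matrix (rows = set A) can be
    supplied instead of sequences.
    """
    if identity is None:
        if not seqs_a or not seqs_b:
            return []
        identity = ani_matrix(seqs_a, seqs_b, k=k, sketch_size=sketch_size, seed=seed)
    if identity.empty:
        return []
    pairs = [
        (float(identity.loc[a, b]), a, b)
        for a in identity.index
        for b in identity.columns
    ]
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    ani_values = [p[0] for p in pairs]
    used_a, used_b = set(), set()
    matches = []
    for i, (ani, a, b) in enumerate(pairs):
        if a in used_a or b in used_b:
            continue
        tie = (i > 0 and ani_values[i - 1] == ani) or (
            i + 1 < len(pairs) and ani_values[i + 1] == ani
        )
        matches.append(
            ANIMatch(
                genome_a=a,
                genome_b=b,
                ani_pct=ani,
                reoccurring=ani > threshold,
                tie_flag=tie,
            )
        )
        used_a.add(a)
        used_b.add(b)
    matches.sort(key=lambda m: m.genome_a)
    return matches
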