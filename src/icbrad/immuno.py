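"""Small immunology statistics accompanying the imaging pipeline.

Covers gene-signature scoring (geometric mean over a gene set), the
immunogram transform (z-scored log2 fold changes between responder and
non-responder group means), TCR-repertoire clonality measures (top-clone
share and normalized-entropy productive clonality), shared CDR3 motif
detection across repertoires (Hamming distance ≤ 1 within a length
stratum), and the LDH-release specific-lysis correction used in ex vivo
cytotoxicity assays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# expression signatures
# ---------------------------------------------------------------------------

def signature_score(
    expression: Mapping[str, float] | pd.Series,
    gene_set: Sequence[str],
    pseudocount: float = 1.0,
) -> float:
    """Geometric mean of the set's gene expression values (+ pseudocount).

    Returns exp(mean(log(x + pseudocount))).  The default pseudocount of 1
    keeps zero counts finite.
    """
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    expr = pd.Series(expression, dtype=float)
    missing = [g for g in gene_set if g not in expr.index]
    if missing:
        raise KeyError(f"genes not in expression table: {missing}")
    x = expr.loc[list(gene_set)].to_numpy() + pseudocount
    if np.any(x <= 0):
        raise ValueError("gene value + pseudocount must be > 0")
    return float(np.exp(np.log(x).mean()))


def signature_scores(
    expression: pd.DataFrame, gene_sets: Mapping[str, Sequence[str]],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-sample signature scores; rows = signatures, columns = samples."""
    return pd.DataFrame(
        {
            name: {
                s: signature_score(expression[s], genes, pseudocount)
                for s in expression.columns
            }
            for name, genes in gene_sets.items()
        }
    ).T


def immunogram(
    responder_means: Mapping[str, float] | pd.Series,
    nonresponder_means: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Immunogram axes: per-feature log2(R/NR), z-scored across features.

    The z-transform uses the sample standard deviation across features; if
    all fold changes are equal the output is all zeros.
    """
    r = pd.Series(responder_means, dtype=float)
    nr = pd.Series(nonresponder_means, dtype=float)
    if not r.index.equals(nr.index):
        nr = nr.reindex(r.index)
    if r.isna().any() or nr.isna().any():
        raise ValueError("feature sets differ between groups")
    if len(r) < 2:
        raise ValueError("need at least 2 features")
    if (r <= 0).any() or (nr <= 0).any():
        raise ValueError("group means must be positive for log2 fold change")
    lfc = np.log2(r / nr)
    sd = lfc.std(ddof=1)
    if sd == 0:
        return lfc * 0.0
    return (lfc - lfc.mean()) / sd


# ---------------------------------------------------------------------------
# TCR repertoires
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Repertoire:
    """Productive CDR3 amino-acid clones with counts for one sample."""

    sample: str
    clones: tuple[tuple[str, int], ...]  # (cdr3_aa, count)

    def __post_init__(self) -> None:
        if any(c <= 0 or c != int(c) for _, c in self.clones):
            raise ValueError("clone counts must be positive integers")
        for seq, _ in self.clones:
            if not seq or not set(seq) <= AA_ALPHABET:
                raise ValueError(f"invalid CDR3 amino-acid sequence: {seq!r}")

    @classmethod
    def from_counts(cls, sample: str, counts: Mapping[str, int]) -> "Repertoire":
        return cls(sample, tuple(sorted(counts.items())))

    @property
    def total(self) -> int:
        return sum(c for _, c in self.clones)

    @property
    def richness(self) -> int:
        return len(self.clones)


def top_clones_share(rep: Repertoire, m: int = 10) -> float:
    """Percentage of all productive sequences carried by the m most
    frequent clones (count ties broken lexicographically)."""
    if rep.richness == 0:
        raise ValueError("empty repertoire")
    ordered = sorted(rep.clones, key=lambda kv: (-kv[1], kv[0]))
    top = sum(c for _, c in ordered[:m])
    return 100.0 * top / rep.total


def productive_clonality(rep: Repertoire) -> float:
    """1 − H/ln(R): Shannon entropy of clone frequencies normalized by log
    richness. 0 = perfectly polyclonal, 1 = monoclonal (single clone, by
    convention)."""
    if rep.richness == 0:
        raise ValueError("empty repertoire")
    if rep.richness == 1:
        return 1.0
    counts = np.array([c for _, c in rep.clones], dtype=float)
    p = counts / counts.sum()
    H = float(-(p * np.log(p)).sum())
    return 1.0 - H / math.log(rep.richness)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class MotifCluster:
    sequences: tuple[str, ...]
    samples: tuple[str, ...]


def shared_cdr3_motifs(
    repertoires: Sequence[Repertoire], max_mismatch: int = 1
) -> list[MotifCluster]:
    """Clusters of equal-length CDR3s within Hamming distance ≤ max_mismatch
    (single linkage per length stratum) that span at least two samples."""
    if len(repertoires) < 2:
        raise ValueError("need at least 2 repertoires")
    seq_samples: dict[str, set[str]] = {}
    for rep in repertoires:
        for seq, _ in rep.clones:
            seq_samples.setdefault(seq, set()).add(rep.sample)

    clusters: list[MotifCluster] = []
    by_len: dict[int, list[str]] = {}
    for seq in sorted(seq_samples):
        by_len.setdefault(len(seq), []).append(seq)
    for length in sorted(by_len):
        seqs = by_len[length]
        parent = list(range(len(seqs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                if hamming(seqs[i], seqs[j]) <= max_mismatch:
                    parent[find(i)] = find(j)
        groups: dict[int, list[str]] = {}
        for i, s in enumerate(seqs):
            groups.setdefault(find(i), []).append(s)
        for members in groups.values():
            samples = sorted(set().union(*(seq_samples[s] for s in members)))
            if len(samples) >= 2:
                clusters.append(MotifCluster(tuple(sorted(members)), tuple(samples)))
    return clusters


# ---------------------------------------------------------------------------
# cytotoxicity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytotoxicityMeasurement:
    """LDH-release optical densities for one effector:target condition."""

    experimental: float
    effector_spontaneous: float
    target_spontaneous: float
    target_maximum: float
    background: float = 0.0

    def __post_init__(self) -> None:
        for name in ("experimental", "effector_spontaneous",
                     "target_spontaneous", "target_maximum", "background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def specific_lysis(m: CytotoxicityMeasurement) -> float:
    """Specific lysis relative to the maximal-lysis control.

    All OD readings are first corrected for culture-medium background; the
    experimental value is then corrected for spontaneous effector and
    target release and normalized by maximal minus spontaneous target
    release (the kit-standard correction):

        (exp − eff_spont − targ_spont + bg) / (targ_max − targ_spont)
    """
    denom = m.target_maximum - m.target_spontaneous
    if denom <= 0:
        raise ValueError("target_maximum must exceed target_spontaneous")
    num = m.experimental - m.effector_spontaneous - m.target_spontaneous + m.background
    return num / denom
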