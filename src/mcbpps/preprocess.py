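"""Fragment/redundancy purging and Henikoff position-based weighting.

Mirrors the standard pre-analysis hygiene for large curated alignments:
sequence fragments and nearly-identical sequences (>98% pairwise identity by
default) are removed, and the survivors are down-weighted for redundancy with
the position-based scheme used by PSI-BLAST (Henikoff & Henikoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .msa import MSA, MSAError


@dataclass
class PreprocessConfig:
    identity_threshold: float = 0.98  # keep pairs at or below this identity
    min_residues: int = 100           # non-gap residues required
    min_coverage: float = 0.5         # fraction of columns non-gap

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.min_residues < 1:
            raise ValueError("min_residues must be >= 1")
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")


def percent_identity(a: str, b: str) -> float:
    """Fraction of jointly non-gap columns at which `a` and `b` agree.

    The denominator is the number of columns where both sequences carry a
    residue — not the alignment length — so fragments cannot pass a high
    threshold on the strength of shared gaps. Returns 0.0 when no column is
    jointly non-gap.
    """
    if len(a) != len(b):
        raise MSAError("percent_identity: sequences differ in length")
    both = 0
    match = 0
    for ca, cb in zip(a, b):
        if ca != "-" and cb != "-":
            both += 1
            if ca == cb:
                match += 1
    return match / both if both else 0.0


def _is_fragment(row: str, length: int, cfg: PreprocessConfig) -> bool:
    n_res = length - row.count("-")
    return n_res < cfg.min_residues or n_res / length < cfg.min_coverage


def purge(
    msa: MSA,
    cfg: PreprocessConfig | None = None,
    protect: set[str] | None = None,
) -> tuple[MSA, list[tuple[str, str]]]:
    """Remove fragments and near-identical sequences, greedily in input order.

    A sequence is kept iff it passes the fragment test (>= ``min_residues``
    non-gap residues and >= ``min_coverage`` column coverage) and its identity
    to every previously kept sequence is <= ``identity_threshold``. Ids in
    `protect` (e.g. seed sequences) are always kept and, like any kept
    sequence, shadow later near-identical ones. Returns the purged alignment
    and a removal log of ``(id, reason)`` pairs, reason being ``"fragment"``
    or ``"redundant:<kept_id>"``.
    """
    cfg = cfg or PreprocessConfig()
    protect = protect or set()
    kept_idx: list[int] = []
    log: list[tuple[str, str]] = []
    for i, (sid, row) in enumerate(zip(msa.ids, msa.rows)):
        if sid in protect:
            kept_idx.append(i)
            continue
        if _is_fragment(row, msa.length, cfg):
            log.append((sid, "fragment"))
            continue
        culprit = None
        for j in kept_idx:
            if percent_identity(row, msa.rows[j]) > cfg.identity_threshold:
                culprit = msa.ids[j]
                break
        if culprit is not None:
            log.append((sid, f"redundant:{culprit}"))
        else:
            kept_idx.append(i)
    if not kept_idx:
        raise MSAError("empty after purge")
    kept_ids = [msa.ids[i] for i in kept_idx]
    return msa.subset(kept_ids), log


def write_removal_log(log: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\treason\n")
        for sid, reason in log:
            fh.write(f"{sid}\t{reason}\n")


def compute_weights(msa: MSA) -> MSA:
    """Attach Henikoff position-based redundancy weights, rescaled to mean 1.

    Per column, each sequence receives 1/(r*s) where r is the number of
    distinct symbols in the column and s the number of sequences carrying
    this sequence's symbol; the gap character counts as a symbol type, as in
    PSI-BLAST. A sequence's raw weight is the mean over columns; final
    weights are rescaled to mean 1.
    """
    X = msa.matrix()
    n, L = X.shape
    raw = np.zeros(n)
    for c in range(L):
        col = X[:, c]
        symbols, inverse, counts = np.unique(
            col, return_inverse=True, return_counts=True
        )
        r = len(symbols)
        raw += 1.0 / (r * counts[inverse])
    raw /= L
    w = raw * n / raw.sum()
    return msa.with_weights(w)
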