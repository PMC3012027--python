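"""Beta-binomial contrast model for alignment columns.

A category's pattern is a set of (column, residue set) positions at which
the foreground sequences are conserved and the background sequences are
divergent. The evidence for one position is a three-part Bayes factor over
weighted match/non-match masses:

    LLR = lbb(mF, uF; aF, bF)                      foreground, conserved prior
        + lbb(mB, uB; A*q, A*(1-q))                background, composition null
        - lbb(mF+mB, uF+uB; A*q, A*(1-q))          pooled, composition null

where lbb(m, u; a, b) = ln B(a+m, b+u) - ln B(a, b) is the beta-binomial
log marginal likelihood of m (weighted) matches and u non-matches under a
Beta(a, b) prior on the match probability, and q is the probability mass of
the residue set under the pooled weighted composition of the alignment.
The foreground prior Beta(9, 1) encodes high conservation; the null
Beta(A*q, A*(1-q)) with concentration A = 20 encodes "no more conserved than
composition predicts". The LLR is positive exactly when splitting the
sequences into this foreground and background explains the column better
than a single pooled model, i.e. when the position discriminates.

Gaps and 'X' are always non-matches and never pattern members: a deletion is
evidence against foreground-style conservation. LLRs are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
from scipy.special import betaln

from .msa import AMINO_ACIDS, MSA, N_AA


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueSet:
    """A nonempty set of canonical amino acids counted as a match."""

    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ModelError("residue set must be nonempty")
        bad = self.members - set(AMINO_ACIDS)
        if bad:
            raise ModelError(f"invalid residue-set members: {sorted(bad)}")

    def __contains__(self, residue: str) -> bool:
        return residue in self.members

    def __len__(self) -> int:
        return len(self.members)

    def __str__(self) -> str:
        # most-frequent-first ordering is not stored; render alphabetically
        s = "".join(sorted(self.members))
        return s if len(s) == 1 else f"[{s}]"


@dataclass
class PatternPosition:
    column: int          # 0-based alignment column
    residues: ResidueSet
    nats: float          # contribution to the posterior log-likelihood ratio
    fg_freq: float = 0.0  # weighted foreground frequency of the set
    bg_freq: float = 0.0


@dataclass
class Pattern:
    """One category's selected positions, distinct columns."""

    category: int
    positions: list[PatternPosition] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = [p.column for p in self.positions]
        if len(set(cols)) != len(cols):
            raise ModelError("pattern has duplicate columns")

    def __len__(self) -> int:
        return len(self.positions)

    def columns(self) -> list[int]:
        return [p.column for p in self.positions]

    def total_nats(self) -> float:
        return sum(p.nats for p in self.positions)


@dataclass
class ColumnCounts:
    """Weighted match/non-match masses for one (column, residue set)."""

    mF: float
    uF: float
    mB: float
    uB: float

    def __post_init__(self) -> None:
        # tolerate float cancellation error from weighted-sum differences
        for name in ("mF", "uF", "mB", "uB"):
            v = getattr(self, name)
            if v < -1e-6:
                raise ModelError("negative count mass")
            if v < 0:
                setattr(self, name, 0.0)


@dataclass
class PriorConfig:
    fg_prior: tuple[float, float] = (9.0, 1.0)
    null_concentration: float = 20.0
    pattern_inclusion_rho: float = 0.02
    max_set_size: int = 4

    def __post_init__(self) -> None:
        if self.fg_prior[0] <= 0 or self.fg_prior[1] <= 0:
            raise ValueError("fg_prior pseudocounts must be positive")
        if self.null_concentration <= 0:
            raise ValueError("null_concentration must be positive")
        if not (0 < self.pattern_inclusion_rho < 1):
            raise ValueError("pattern_inclusion_rho must be in (0, 1)")
        if self.max_set_size < 1:
            raise ValueError("max_set_size must be >= 1")

    @property
    def log_rho_odds(self) -> float:
        """ln(rho/(1-rho)): the per-position inclusion penalty."""
        rho = self.pattern_inclusion_rho
        return log(rho / (1.0 - rho))


def lbb(m, u, a, b):
    """Beta-binomial log marginal likelihood (unnormalized in m, u)."""
    return betaln(a + m, b + u) - betaln(a, b)


def pooled_composition(msa: MSA) -> np.ndarray:
    """Weighted amino-acid composition of the whole alignment.

    Length-20 probability vector over AMINO_ACIDS; gaps and 'X' excluded;
    one pseudocount per residue type keeps every entry positive.
    """
    X = msa.matrix()
    w = msa.weights if msa.weights is not None else np.ones(msa.n)
    counts = np.ones(N_AA)
    for a in range(N_AA):
        counts[a] += (w[:, None] * (X == a)).sum()
    return counts / counts.sum()


def set_probability(rset: ResidueSet, composition: np.ndarray) -> float:
    q = sum(composition[AMINO_ACIDS.index(r)] for r in rset.members)
    return float(min(max(q, 1e-9), 1 - 1e-9))


def column_counts(
    msa: MSA,
    weights: np.ndarray,
    fg_ids: list[str],
    bg_ids: list[str],
    column: int,
    rset: ResidueSet,
) -> ColumnCounts:
    """Weighted match/non-match tallies at `column` for the given partition.

    Gaps and 'X' accrue to the non-match mass.
    """
    if not fg_ids or not bg_ids:
        raise ModelError("foreground and background must be nonempty")
    if set(fg_ids) & set(bg_ids):
        raise ModelError("foreground and background overlap")
    if not (0 <= column < msa.length):
        raise ModelError(f"column {column} out of range")
    member_codes = {AMINO_ACIDS.index(r) for r in rset.members}
    X = msa.matrix()

    def tally(ids: list[str]) -> tuple[float, float]:
        m = u = 0.0
        for sid in ids:
            i = msa.index_of(sid)
            if X[i, column] in member_codes:
                m += weights[i]
            else:
                u += weights[i]
        return m, u

    mF, uF = tally(fg_ids)
    mB, uB = tally(bg_ids)
    return ColumnCounts(mF, uF, mB, uB)


def column_llr(counts: ColumnCounts, priors: PriorConfig, q: float) -> float:
    """Per-position evidence in nats; positive favors a discriminating split."""
    if not (0 < q < 1):
        raise ModelError("q must be in (0, 1)")
    aF, bF = priors.fg_prior
    A = priors.null_concentration
    a0, b0 = A * q, A * (1.0 - q)
    return float(
        lbb(counts.mF, counts.uF, aF, bF)
        + lbb(counts.mB, counts.uB, a0, b0)
        - lbb(counts.mF + counts.mB, counts.uF + counts.uB, a0, b0)
    )


def column_llr_arrays(mF, uF, mB, uB, priors: PriorConfig, q):
    """Vectorized :func:`column_llr` over aligned count arrays."""
    aF, bF = priors.fg_prior
    A = priors.null_concentration
    a0, b0 = A * np.asarray(q), A * (1.0 - np.asarray(q))
    return (
        betaln(aF + mF, bF + uF)
        - betaln(aF, bF)
        + betaln(a0 + mB, b0 + uB)
        - betaln(a0, b0)
        - betaln(a0 + mF + mB, b0 + uF + uB)
        + betaln(a0, b0)
    )


def set_size_log_prior(k: int) -> float:
    """ln prior of choosing one particular size-k residue set: -ln C(20, k).

    The uniform Occam factor over same-size sets; without it the selection
    of the top-k foreground residues earns a spurious evidence bonus that
    grows with k.
    """
    from math import comb

    return -log(comb(N_AA, k))


def best_residue_set_from_counts(
    fg_counts: np.ndarray,
    bg_counts: np.ndarray,
    fg_nonmatch_total: float,
    bg_nonmatch_total: float,
    composition: np.ndarray,
    priors: PriorConfig,
) -> tuple[ResidueSet, float, ColumnCounts] | None:
    """Pick the nested residue set maximizing the set-prior-penalized LLR.

    `fg_counts`/`bg_counts` are weighted per-amino-acid masses at one column
    (length 20); the totals include gap/'X' mass. Candidates are the nested
    sets {top1}, {top1, top2}, ... by foreground frequency, up to
    ``max_set_size``; a candidate is eligible only if its weighted foreground
    frequency exceeds its background frequency (the pattern must be conserved
    in the foreground, not merely different). The maximized objective is
    ``column_llr + set_size_log_prior(k)``; ties between equal-frequency
    residues break toward the alphabetically earlier residue, ties in the
    objective toward the smaller set. The returned nats are the raw LLR of
    the winning set. Returns None when the foreground is all-gap or no
    candidate is eligible.
    """
    fg_total = fg_counts.sum() + fg_nonmatch_total
    bg_total = bg_counts.sum() + bg_nonmatch_total
    if fg_counts.sum() <= 0:
        return None
    order = np.lexsort((np.arange(N_AA), -fg_counts))
    best = None
    best_obj = -np.inf
    mF = mB = qsum = 0.0
    members: list[str] = []
    for k in range(min(priors.max_set_size, int((fg_counts > 0).sum()))):
        a = order[k]
        members.append(AMINO_ACIDS[a])
        mF += fg_counts[a]
        mB += bg_counts[a]
        qsum += composition[a]
        if bg_total > 0 and mF / fg_total <= mB / bg_total:
            continue
        q = min(max(qsum, 1e-9), 1 - 1e-9)
        counts = ColumnCounts(mF, fg_total - mF, mB, bg_total - mB)
        llr = column_llr(counts, priors, q)
        obj = llr + set_size_log_prior(len(members))
        if obj > best_obj + 1e-12:
            best = (ResidueSet(frozenset(members)), llr, counts)
            best_obj = obj
    return best


def best_residue_set(
    msa: MSA,
    weights: np.ndarray,
    fg_ids: list[str],
    bg_ids: list[str],
    column: int,
    priors: PriorConfig,
    composition: np.ndarray | None = None,
) -> tuple[ResidueSet, float] | None:
    """Best discriminating residue set at `column`, or None if fg is all-gap."""
    if not fg_ids:
        raise ModelError("foreground must be nonempty")
    if composition is None:
        composition = pooled_composition(msa)
    X = msa.matrix()
    fg_idx = [msa.index_of(s) for s in fg_ids]
    bg_idx = [msa.index_of(s) for s in bg_ids]
    fg_counts = np.zeros(N_AA)
    bg_counts = np.zeros(N_AA)
    fg_nm = bg_nm = 0.0
    for i in fg_idx:
        c = X[i, column]
        if c < N_AA:
            fg_counts[c] += weights[i]
        else:
            fg_nm += weights[i]
    for i in bg_idx:
        c = X[i, column]
        if c < N_AA:
            bg_counts[c] += weights[i]
        else:
            bg_nm += weights[i]
    res = best_residue_set_from_counts(
        fg_counts, bg_counts, fg_nm, bg_nm, composition, priors
    )
    if res is None:
        return None
    rset, llr, _ = res
    return rset, llr
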