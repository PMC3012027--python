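"""Gibbs sampler jointly assigning sequences to subgroups and selecting patterns.

The sampler alternates two sweeps until convergence:

* an assignment sweep, in which every non-seed sequence is reassigned to a
  hyperpartition row with probability proportional to the exponentiated
  change in the total log-posterior (or to the argmax in greedy mode) —
  seed sequences never move;
* a pattern sweep, in which each category's pattern is re-selected column by
  column: a column enters the pattern when its best residue set's evidence
  exceeds the inclusion penalty ln(rho/(1-rho)), and residue sets of
  retained columns are refreshed.

Because every greedy move maximizes an exact conditional of the same joint
objective, the greedy-mode log-posterior is non-decreasing across sweeps.
In sample mode the assignment temperature anneals geometrically toward
greedy, which mitigates the multimodality of the joint partition/pattern
posterior.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from math import log
from pathlib import Path

import numpy as np

from .hyperpartition import BG, FG, Hyperpartition, validate
from .model import (
    Pattern,
    PatternPosition,
    PriorConfig,
    best_residue_set_from_counts,
    column_llr_arrays,
    pooled_composition,
    set_size_log_prior,
)
from .msa import MSA, N_AA, ALPHABET, SeedAlignment
from .preprocess import percent_identity


class SamplerError(ValueError):
    pass


@dataclass
class SamplerConfig:
    max_sweeps: int = 500
    convergence_patience: int = 3    # consecutive zero-change sweeps
    anneal_start: float = 2.0        # initial temperature (sample mode)
    anneal_factor: float = 0.98      # per-sweep geometric cooling
    mode: str = "greedy"             # "greedy" | "sample"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")
        if self.convergence_patience < 1:
            raise ValueError("convergence_patience must be >= 1")
        if self.mode not in ("greedy", "sample"):
            raise ValueError("mode must be 'greedy' or 'sample'")


@dataclass
class SamplerState:
    """A snapshot of the sampler: assignments, patterns, and the posterior."""

    assignment: dict[str, str]
    patterns: list[Pattern]
    log_posterior: float
    iteration: int
    rng_seed: int


@dataclass
class TraceRow:
    sweep: int
    log_posterior: float
    n_reassigned: int
    total_pattern_positions: int


def write_trace(trace: list[TraceRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sweep\tlog_posterior\tn_reassigned\ttotal_pattern_positions\n")
        for r in trace:
            fh.write(
                f"{r.sweep}\t{r.log_posterior:.6f}\t{r.n_reassigned}"
                f"\t{r.total_pattern_positions}\n"
            )


def _weighted_symbol_counts(X: np.ndarray, w: np.ndarray, mask: np.ndarray):
    """(n_symbols, L) weighted residue counts over the masked sequences."""
    L = X.shape[1]
    sub = X[mask]
    ws = w[mask]
    if sub.size == 0:
        return np.zeros((len(ALPHABET), L))
    flat = sub.astype(np.int64) * L + np.arange(L)[None, :]
    acc = np.bincount(
        flat.ravel(),
        weights=np.repeat(ws, L),
        minlength=len(ALPHABET) * L,
    )
    return acc.reshape(len(ALPHABET), L)


class McBppsSampler:
    """Joint sampler over sequence assignments and category patterns.

    Parameters
    ----------
    msa:
        The main alignment; redundancy weights are used when present,
        otherwise unit weights.
    hp:
        A validated hyperpartition (a Rejected row is appended when absent).
    seeds:
        One :class:`SeedAlignment` per modeled subgroup. Seed sequence ids
        must occur in the main alignment; they stay fixed to their subgroup.
    """

    def __init__(
        self,
        msa: MSA,
        hp: Hyperpartition,
        seeds: list[SeedAlignment],
        priors: PriorConfig | None = None,
        config: SamplerConfig | None = None,
    ) -> None:
        self.priors = priors or PriorConfig()
        self.config = config or SamplerConfig()
        hp = hp.with_rejected_row()
        violations = validate(hp)
        if violations:
            raise SamplerError(f"invalid hyperpartition: {violations}")
        self.hp = hp
        self.msa = msa
        self.X = msa.matrix()
        self.w = (
            msa.weights if msa.weights is not None else np.ones(msa.n)
        ).astype(float)
        self.composition = pooled_composition(msa)
        self.n_rows = hp.n_subgroups
        self.M = hp.n_categories

        self.seed_row: dict[str, int] = {}
        self.seeds = seeds
        for seed in seeds:
            seed.check_against(msa)
            try:
                row = hp.row_index(seed.subgroup_name)
            except KeyError:
                raise SamplerError(
                    f"seed subgroup {seed.subgroup_name!r} is not a "
                    "hyperpartition row"
                ) from None
            for sid in seed.msa.ids:
                if sid not in msa.ids:
                    raise SamplerError(
                        f"seed sequence {sid!r} not in the main alignment"
                    )
                self.seed_row[sid] = row

        self.fixed = np.zeros(msa.n, dtype=bool)
        self.row_of = np.zeros(msa.n, dtype=np.int64)
        for sid, row in self.seed_row.items():
            i = msa.index_of(sid)
            self.fixed[i] = True
            self.row_of[i] = row

        # role of each row in each category, as +1 (FG), -1 (BG), 0 (OMIT)
        self.role = np.zeros((self.n_rows, self.M), dtype=np.int8)
        for i in range(self.n_rows):
            for j in range(self.M):
                c = hp.cell(i, j)
                self.role[i, j] = 1 if c == FG else (-1 if c == BG else 0)

        self.rng = np.random.default_rng(self.config.rng_seed)
        self.patterns: list[Pattern] = [Pattern(j) for j in range(self.M)]
        self._caches: list[dict] = [self._empty_cache() for _ in range(self.M)]
        self.trace: list[TraceRow] = []
        self.iteration = 0

    # -- caches ------------------------------------------------------------

    @staticmethod
    def _empty_cache() -> dict:
        return {
            "cols": np.zeros(0, dtype=np.int64),
            "setmask": np.zeros((0, len(ALPHABET)), dtype=bool),
            "match": None,
            "q": np.zeros(0),
            "mF": np.zeros(0),
            "uF": np.zeros(0),
            "mB": np.zeros(0),
            "uB": np.zeros(0),
        }

    def _rebuild_cache(self, j: int) -> None:
        pat = self.patterns[j]
        cache = self._empty_cache()
        k = len(pat)
        if k:
            cols = np.array(pat.columns(), dtype=np.int64)
            setmask = np.zeros((k, len(ALPHABET)), dtype=bool)
            qv = np.zeros(k)
            for p, pos in enumerate(pat.positions):
                for r in pos.residues.members:
                    setmask[p, ALPHABET.index(r)] = True
                qv[p] = self._set_q(pos.residues.members)
            match = setmask[np.arange(k)[None, :], self.X[:, cols]]
            fg_mask, bg_mask = self._partition_masks(j)
            wf = np.where(fg_mask, self.w, 0.0)
            wb = np.where(bg_mask, self.w, 0.0)
            cache.update(
                cols=cols,
                setmask=setmask,
                match=match,
                q=qv,
                mF=(wf[:, None] * match).sum(axis=0),
                uF=(wf[:, None] * ~match).sum(axis=0),
                mB=(wb[:, None] * match).sum(axis=0),
                uB=(wb[:, None] * ~match).sum(axis=0),
            )
        self._caches[j] = cache

    def _set_q(self, members) -> float:
        q = sum(self.composition[ALPHABET.index(r)] for r in members)
        return float(min(max(q, 1e-9), 1 - 1e-9))

    def _partition_masks(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        roles = self.role[self.row_of, j]
        return roles == 1, roles == -1

    # -- scoring -----------------------------------------------------------

    def _detach(self, i: int) -> None:
        """Remove sequence i's mass from every category's counts."""
        wi = self.w[i]
        for j in range(self.M):
            cache = self._caches[j]
            if cache["match"] is None:
                continue
            role = self.role[self.row_of[i], j]
            if role == 0:
                continue
            m = cache["match"][i]
            if role == 1:
                cache["mF"] -= wi * m
                cache["uF"] -= wi * ~m
            else:
                cache["mB"] -= wi * m
                cache["uB"] -= wi * ~m

    def _attach(self, i: int, row: int) -> None:
        wi = self.w[i]
        self.row_of[i] = row
        for j in range(self.M):
            cache = self._caches[j]
            if cache["match"] is None:
                continue
            role = self.role[row, j]
            if role == 0:
                continue
            m = cache["match"][i]
            if role == 1:
                cache["mF"] += wi * m
                cache["uF"] += wi * ~m
            else:
                cache["mB"] += wi * m
                cache["uB"] += wi * ~m

    def _row_scores_detached(self, i: int) -> np.ndarray:
        """Log score per row for sequence i, with i detached from counts.

        The score is the exact change in total log-posterior from attaching
        the sequence to the row; a row omitted in every category scores 0.
        """
        wi = self.w[i]
        delta = np.zeros((self.M, 3))  # columns: role -1, 0, +1
        for j in range(self.M):
            cache = self._caches[j]
            if cache["match"] is None:
                continue
            m = cache["match"][i].astype(float)
            base = column_llr_arrays(
                cache["mF"], cache["uF"], cache["mB"], cache["uB"],
                self.priors, cache["q"],
            )
            plus = column_llr_arrays(
                cache["mF"] + wi * m, cache["uF"] + wi * (1 - m),
                cache["mB"], cache["uB"], self.priors, cache["q"],
            )
            minus = column_llr_arrays(
                cache["mF"], cache["uF"],
                cache["mB"] + wi * m, cache["uB"] + wi * (1 - m),
                self.priors, cache["q"],
            )
            delta[j, 2] = (plus - base).sum()
            delta[j, 0] = (minus - base).sum()
        scores = np.zeros(self.n_rows)
        for r in range(self.n_rows):
            scores[r] = delta[np.arange(self.M), self.role[r] + 1].sum()
        return scores

    def score_sequence(self, sid: str, row: int | str) -> float:
        """Log score of placing `sid` in `row` (exact posterior change)."""
        if isinstance(row, str):
            row = self.hp.row_index(row)
        i = self.msa.index_of(sid)
        self._detach(i)
        scores = self._row_scores_detached(i)
        self._attach(i, self.row_of[i])
        return float(scores[row])

    def membership_probabilities(self, sid: str) -> dict[str, float]:
        """Softmax over rows of the per-row log scores; sums to 1."""
        i = self.msa.index_of(sid)
        self._detach(i)
        scores = self._row_scores_detached(i)
        self._attach(i, self.row_of[i])
        z = scores - scores.max()
        p = np.exp(z)
        p /= p.sum()
        return dict(zip(self.hp.subgroup_names, p.tolist()))

    # -- sweeps ------------------------------------------------------------

    def sweep_assignments(self, temperature: float = 0.0) -> int:
        """Reassign every non-seed sequence; returns the number of moves.

        With ``temperature <= 0`` (or greedy mode) each sequence moves to the
        argmax row, ties keeping the current row; otherwise the row is
        sampled with probability proportional to exp(score/temperature).
        """
        greedy = self.config.mode == "greedy" or temperature <= 1e-6
        n_moved = 0
        for i in range(self.msa.n):
            if self.fixed[i]:
                continue
            old = self.row_of[i]
            self._detach(i)
            scores = self._row_scores_detached(i)
            if greedy:
                best = scores.max()
                new = old if scores[old] >= best - 1e-9 else int(scores.argmax())
            else:
                z = (scores - scores.max()) / temperature
                p = np.exp(z)
                p /= p.sum()
                new = int(self.rng.choice(self.n_rows, p=p))
            self._attach(i, new)
            if new != old:
                n_moved += 1
        return n_moved

    def sweep_patterns(self, temperature: float = 0.0) -> bool:
        """Re-select every category's pattern; returns True if any changed.

        Every column is a candidate: its best nested residue set is found
        and the column is included when the penalized evidence
        LLR + set-choice prior + ln(rho/(1-rho)) is positive (greedy) or
        with the corresponding sigmoid probability (sample mode). For a
        column already in the pattern the incumbent residue set competes
        with the re-derived one, so a greedy sweep never lowers the
        posterior.
        """
        greedy = self.config.mode == "greedy" or temperature <= 1e-6
        penalty = self.priors.log_rho_odds
        changed = False
        L = self.msa.length
        for j in range(self.M):
            fg_mask, bg_mask = self._partition_masks(j)
            old = {p.column: p for p in self.patterns[j].positions}
            new_positions: list[PatternPosition] = []
            if fg_mask.any() and bg_mask.any():
                fgc = _weighted_symbol_counts(self.X, self.w, fg_mask)
                bgc = _weighted_symbol_counts(self.X, self.w, bg_mask)
                for c in range(L):
                    cand = best_residue_set_from_counts(
                        fgc[:N_AA, c],
                        bgc[:N_AA, c],
                        float(fgc[N_AA:, c].sum()),
                        float(bgc[N_AA:, c].sum()),
                        self.composition,
                        self.priors,
                    )
                    if c in old:
                        # incumbent set competes, for monotone greedy sweeps
                        inc = self._evaluate_set(
                            old[c].residues.members, fgc[:, c], bgc[:, c]
                        )
                        if cand is None or inc[1] + set_size_log_prior(
                            len(inc[0])
                        ) > cand[1] + set_size_log_prior(len(cand[0])):
                            cand = inc
                    if cand is None:
                        continue
                    rset, llr, counts = cand
                    gain = llr + set_size_log_prior(len(rset)) + penalty
                    if greedy:
                        include = gain > 0
                    else:
                        p_inc = 1.0 / (1.0 + np.exp(-gain / temperature))
                        include = self.rng.random() < p_inc
                    if include:
                        fg_tot = counts.mF + counts.uF
                        bg_tot = counts.mB + counts.uB
                        new_positions.append(
                            PatternPosition(
                                column=c,
                                residues=rset,
                                nats=llr,
                                fg_freq=counts.mF / fg_tot if fg_tot else 0.0,
                                bg_freq=counts.mB / bg_tot if bg_tot else 0.0,
                            )
                        )
            new_pat = Pattern(j, new_positions)
            if (
                new_pat.columns() != self.patterns[j].columns()
                or [p.residues for p in new_pat.positions]
                != [p.residues for p in self.patterns[j].positions]
            ):
                changed = True
            self.patterns[j] = new_pat
            self._rebuild_cache(j)
        return changed

    def _evaluate_set(self, members, fg_col, bg_col):
        from .model import ColumnCounts, ResidueSet, column_llr

        codes = [ALPHABET.index(r) for r in members]
        mF = float(fg_col[codes].sum())
        mB = float(bg_col[codes].sum())
        counts = ColumnCounts(
            mF, float(fg_col.sum()) - mF, mB, float(bg_col.sum()) - mB
        )
        q = self._set_q(members)
        rset = ResidueSet(frozenset(members))
        return rset, column_llr(counts, self.priors, q), counts

    # -- posterior ---------------------------------------------------------

    def total_log_posterior(self) -> float:
        """Recompute the joint objective from scratch.

        Sum over categories of per-position LLRs plus the inclusion penalty
        per position, plus the uniform assignment prior over rows for
        non-seed sequences.
        """
        total = 0.0
        penalty = self.priors.log_rho_odds
        for j in range(self.M):
            fg_mask, bg_mask = self._partition_masks(j)
            pat = self.patterns[j]
            if not len(pat) or not fg_mask.any() or not bg_mask.any():
                continue
            fgc = _weighted_symbol_counts(self.X, self.w, fg_mask)
            bgc = _weighted_symbol_counts(self.X, self.w, bg_mask)
            for pos in pat.positions:
                _, llr, _ = self._evaluate_set(
                    pos.residues.members, fgc[:, pos.column], bgc[:, pos.column]
                )
                total += llr + set_size_log_prior(len(pos.residues)) + penalty
        n_free = int((~self.fixed).sum())
        total += -n_free * log(self.n_rows)
        return total

    # -- initialization & run ----------------------------------------------

    def initialize(self) -> None:
        """Nearest-seed start: each non-seed sequence goes to the subgroup
        whose seed alignment contains its highest-identity seed; ties
        (including all-zero identity) go to Rejected."""
        rej = self.hp.rejected_index
        if rej is None:  # with_rejected_row guarantees presence
            raise SamplerError("hyperpartition lacks a Rejected row")
        seed_rows = []
        seed_strs = []
        for seed in self.seeds:
            row = self.hp.row_index(seed.subgroup_name)
            for srow in seed.msa.rows:
                seed_rows.append(row)
                seed_strs.append(srow)
        for i in range(self.msa.n):
            if self.fixed[i]:
                continue
            best_by_row: dict[int, float] = {}
            for row, s in zip(seed_rows, seed_strs):
                pid = percent_identity(self.msa.rows[i], s)
                if pid > best_by_row.get(row, -1.0):
                    best_by_row[row] = pid
            if not best_by_row:
                self.row_of[i] = rej
                continue
            top = max(best_by_row.values())
            winners = [r for r, v in best_by_row.items() if v >= top - 1e-12]
            self.row_of[i] = winners[0] if len(winners) == 1 and top > 0 else rej
        for j in range(self.M):
            fg_mask, _ = self._partition_masks(j)
            if not fg_mask.any():
                raise SamplerError(
                    f"category {self.hp.category_names[j]!r} has an empty "
                    "foreground after initialization"
                )
        self.sweep_patterns(temperature=0.0)

    def state(self) -> SamplerState:
        assignment = {
            sid: self.hp.subgroup_names[self.row_of[i]]
            for i, sid in enumerate(self.msa.ids)
        }
        return SamplerState(
            assignment=assignment,
            patterns=copy.deepcopy(self.patterns),
            log_posterior=self.total_log_posterior(),
            iteration=self.iteration,
            rng_seed=self.config.rng_seed,
        )

    def run(self) -> tuple[SamplerState, list[TraceRow]]:
        """Alternate sweeps until convergence; return the best state visited."""
        self.initialize()
        cfg = self.config
        T = cfg.anneal_start if cfg.mode == "sample" else 0.0
        best_lp = -np.inf
        best_rows = None
        best_patterns = None
        quiet = 0
        for sweep in range(1, cfg.max_sweeps + 1):
            self.iteration = sweep
            n_moved = self.sweep_assignments(temperature=T)
            pat_changed = self.sweep_patterns(temperature=T)
            lp = self.total_log_posterior()
            self.trace.append(
                TraceRow(
                    sweep,
                    lp,
                    n_moved,
                    sum(len(p) for p in self.patterns),
                )
            )
            if lp > best_lp:
                best_lp = lp
                best_rows = self.row_of.copy()
                best_patterns = copy.deepcopy(self.patterns)
            quiet = quiet + 1 if (n_moved == 0 and not pat_changed) else 0
            if quiet >= cfg.convergence_patience:
                break
            if cfg.mode == "sample":
                T *= cfg.anneal_factor
        # restore the best state visited
        if best_rows is not None:
            self.row_of = best_rows
            self.patterns = best_patterns
            for j in range(self.M):
                self._rebuild_cache(j)
        # assertable invariant: seeds never moved
        for sid, row in self.seed_row.items():
            assert self.row_of[self.msa.index_of(sid)] == row
        return self.state(), self.trace


def run(
    msa: MSA,
    hp: Hyperpartition,
    seeds: list[SeedAlignment],
    priors: PriorConfig | None = None,
    config: SamplerConfig | None = None,
) -> tuple[SamplerState, list[TraceRow], McBppsSampler]:
    """Convenience wrapper: build a sampler, run it, return (state, trace, sampler)."""
    sampler = McBppsSampler(msa, hp, seeds, priors, config)
    state, trace = sampler.run()
    return state, trace, sampler


def write_assignment(
    state: SamplerState, sampler: McBppsSampler, path: str | Path
) -> None:
    """Final assignment TSV: id, subgroup, membership probability of that row."""
    with open(path, "w") as fh:
        fh.write("id\tsubgroup\tprobability\n")
        for sid in sampler.msa.ids:
            sub = state.assignment[sid]
            prob = sampler.membership_probabilities(sid)[sub]
            fh.write(f"{sid}\t{sub}\t{prob:.6f}\n")
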