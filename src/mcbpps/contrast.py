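"""Contrast alignments and pattern-information reports.

A contrast alignment displays, for one category: the seed sequences of a
foreground subgroup; directly below, the foreground pattern residues at the
displayed pattern columns; their weighted residue frequencies in integer
tenths ('8' means the pattern residue occurs in 80%-90% of the weighted
foreground); the background pattern and frequencies (prefixed ``bg|`` in
this plain-text rendering); and a histogram of relative selective constraint
above the alignment. The contrast setting chooses how many of the
top-evidence pattern positions are highlighted. The quantitative per-position
evidence (in nats) goes to the pattern-information TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .model import Pattern, PatternPosition
from .msa import MSA, SeedAlignment
from .sampler import McBppsSampler, SamplerState


def freq_digit(f: float) -> str:
    """Integer-tenths digit of a weighted frequency: floor(10*f), clamped to 9.

    '8' covers 80%-90%; f = 1.0 renders '9' so a cell stays one character.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"frequency {f} outside [0, 1]")
    return str(min(int(10.0 * f), 9))


def select_displayed(pattern: Pattern, contrast_setting: int) -> list[int]:
    """Columns of the `contrast_setting` highest-nats positions.

    Ties break toward the lower column index; a setting at or above the
    pattern size displays every position.
    """
    if contrast_setting < 1:
        raise ValueError("contrast_setting must be >= 1")
    ranked = sorted(pattern.positions, key=lambda p: (-p.nats, p.column))
    return sorted(p.column for p in ranked[:contrast_setting])


@dataclass
class ContrastAlignment:
    category_name: str
    seed_rows: list[tuple[str, str]]
    fg_pattern_line: str
    fg_digit_line: str
    bg_pattern_line: str
    bg_digit_line: str
    histogram_line: str
    displayed_columns: list[int]
    rejected: bool = False

    def text(self) -> str:
        if self.rejected:
            return (
                f"== category {self.category_name}: rejected "
                "(no pattern has empirical support) ==\n"
            )
        label_w = max(
            [len(sid) for sid, _ in self.seed_rows]
            + [len("bg|wt_res_freqs:")]
        )
        lines = [f"== category {self.category_name} =="]
        lines.append(f"{'constraint:':<{label_w}} {self.histogram_line}")
        for sid, row in self.seed_rows:
            lines.append(f"{sid:<{label_w}} {row}")
        lines.append(f"{'pattern:':<{label_w}} {self.fg_pattern_line}")
        lines.append(f"{'wt_res_freqs:':<{label_w}} {self.fg_digit_line}")
        lines.append(f"{'bg|pattern:':<{label_w}} {self.bg_pattern_line}")
        lines.append(f"{'bg|wt_res_freqs:':<{label_w}} {self.bg_digit_line}")
        return "\n".join(lines) + "\n"


_HIST_CHARS = " 123456789!"  # bar heights 0..10, one character each


def _histogram_heights(positions: list[PatternPosition]) -> dict[int, int]:
    """Per-column bar heights 1-10, a linear rescale of nats over the
    displayed positions (a relative, qualitative measure)."""
    if not positions:
        return {}
    top = max(p.nats for p in positions)
    if top <= 0:
        return {p.column: 1 for p in positions}
    return {
        p.column: max(1, min(10, int(round(10.0 * p.nats / top))))
        for p in positions
    }


def render(
    sampler: McBppsSampler,
    state: SamplerState,
    category: int,
    seeds: list[SeedAlignment],
    contrast_setting: int = 10,
    fg_subgroup: str | None = None,
) -> ContrastAlignment:
    """Build the contrast alignment of one category.

    Seed rows come from `fg_subgroup` (default: the first foreground row
    that has a seed alignment). Foreground/background digits are the
    weighted frequencies of each position's residue set in the respective
    partitions, re-read from the sampler's current counts.
    """
    hp = sampler.hp
    name = hp.category_names[category]
    pattern = state.patterns[category]
    L = sampler.msa.length
    if len(pattern) == 0:
        return ContrastAlignment(name, [], "", "", "", "", "", [], rejected=True)

    displayed = set(select_displayed(pattern, contrast_setting))
    shown = [p for p in pattern.positions if p.column in displayed]

    fg_rows = {
        hp.subgroup_names[i]
        for i in range(hp.n_subgroups)
        if hp.cell(i, category) == "+"
    }
    seed_by_group = {s.subgroup_name: s for s in seeds}
    if fg_subgroup is None:
        fg_subgroup = next(
            (g for g in hp.subgroup_names if g in fg_rows and g in seed_by_group),
            None,
        )
    seed_rows: list[tuple[str, str]] = []
    if fg_subgroup is not None and fg_subgroup in seed_by_group:
        seed = seed_by_group[fg_subgroup]
        seed_rows = list(zip(seed.msa.ids, seed.msa.rows))

    fg_pat = ["."] * L
    fg_dig = ["."] * L
    bg_pat = ["."] * L
    bg_dig = ["."] * L
    for p in shown:
        # show the set's alphabetically first residue; full set in the TSV
        r = min(p.residues.members)
        fg_pat[p.column] = r
        fg_dig[p.column] = freq_digit(p.fg_freq)
        bg_pat[p.column] = r
        bg_dig[p.column] = freq_digit(p.bg_freq)

    heights = _histogram_heights(shown)
    hist = "".join(_HIST_CHARS[heights.get(c, 0)] for c in range(L))

    return ContrastAlignment(
        category_name=name,
        seed_rows=seed_rows,
        fg_pattern_line="".join(fg_pat),
        fg_digit_line="".join(fg_dig),
        bg_pattern_line="".join(bg_pat),
        bg_digit_line="".join(bg_dig),
        histogram_line=hist,
        displayed_columns=sorted(displayed),
    )


def reference_labels(seed: SeedAlignment | None, pattern: Pattern) -> dict[int, str]:
    """Map pattern columns to seed-numbered residue labels (e.g. 'D26').

    Numbering counts non-gap residues of the seed's first sequence; a column
    where the seed has a gap is labeled '-'.
    """
    labels: dict[int, str] = {}
    if seed is None:
        return {p.column: "-" for p in pattern.positions}
    row = seed.msa.rows[0]
    number = 0
    numbering: dict[int, str] = {}
    for c, ch in enumerate(row):
        if ch != "-":
            number += 1
            numbering[c] = f"{ch}{number}"
    for p in pattern.positions:
        labels[p.column] = numbering.get(p.column, "-")
    return labels


def write_pattern_info(
    sampler: McBppsSampler,
    state: SamplerState,
    seeds: list[SeedAlignment],
    path: str | Path,
) -> None:
    """Quantitative per-position report: one row per (category, column).

    Columns: category, 1-based alignment column, reference-sequence label,
    residue set, nats, weighted foreground frequency, weighted background
    frequency; sorted by category then nats descending.
    """
    hp = sampler.hp
    seed_by_group = {s.subgroup_name: s for s in seeds}
    with open(path, "w") as fh:
        fh.write("category\tcolumn\tref_label\tresidue_set\tnats\tfg_freq\tbg_freq\n")
        for j, pattern in enumerate(state.patterns):
            fg_seed = next(
                (
                    seed_by_group[hp.subgroup_names[i]]
                    for i in range(hp.n_subgroups)
                    if hp.cell(i, j) == "+"
                    and hp.subgroup_names[i] in seed_by_group
                ),
                None,
            )
            labels = reference_labels(fg_seed, pattern)
            for p in sorted(pattern.positions, key=lambda p: (-p.nats, p.column)):
                fh.write(
                    f"{hp.category_names[j]}\t{p.column + 1}\t"
                    f"{labels[p.column]}\t{p.residues}\t{p.nats:.6f}\t"
                    f"{p.fg_freq:.6f}\t{p.bg_freq:.6f}\n"
                )
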