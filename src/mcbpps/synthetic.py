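"""Synthetic subgroup-structured alignments with planted patterns.

The generator emulates the statistical structure the sampler targets:
alignment columns at which a category's foreground subgroups are conserved
(a residue from a small set appears with probability ``pF``, default 0.9)
while background subgroups are divergent (set frequency ``pB``, default
0.1), embedded in columns of undifferentiated background composition.
Decoy sequences model pseudogene products and other aberrant homologs as
pure-composition sequences carrying no subgroup signal; optional duplicates
and fragments exercise the preprocessing rules. It does not emulate
phylogenetic realism — no indel process, rate variation, or within-subgroup
tree structure — so recovery results speak to pattern/partition inference,
not to alignment quality on real families.

Every draw is a function of ``rng_seed``: the same spec yields byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hyperpartition import (
    FG,
    BG,
    REJECTED,
    Hyperpartition,
    write_hyperpartition,
)
from .model import ResidueSet
from .msa import AMINO_ACIDS, MSA, SeedAlignment, write_alignment


@dataclass
class PlantedPosition:
    column: int                # 0-based
    residues: frozenset[str]


@dataclass
class SyntheticSpec:
    hyperpartition: Hyperpartition
    seqs_per_subgroup: dict[str, int]
    length: int
    planted: dict[str, list[PlantedPosition]]  # category name -> positions
    fg_conservation: float = 0.9   # pF
    bg_set_freq: float = 0.1       # pB
    background: np.ndarray | None = None  # composition over 20 aa
    n_decoys: int = 0
    n_duplicates: int = 0
    n_fragments: int = 0
    seeds_per_subgroup: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.bg_set_freq < self.fg_conservation <= 1):
            raise ValueError("need 0 <= pB < pF <= 1")
        if self.background is None:
            self.background = np.full(len(AMINO_ACIDS), 1 / len(AMINO_ACIDS))
        for cat, positions in self.planted.items():
            if cat not in self.hyperpartition.category_names:
                raise ValueError(f"planted category {cat!r} not in hyperpartition")
            for p in positions:
                if not (0 <= p.column < self.length):
                    raise ValueError(f"planted column {p.column} out of range")
                ResidueSet(frozenset(p.residues))  # validates members
        for name, n in self.seqs_per_subgroup.items():
            if n < 0:
                raise ValueError("sequence counts must be >= 0")
            self.hyperpartition.row_index(name)  # must exist


@dataclass
class Truth:
    assignment: dict[str, str]                 # id -> subgroup (or Rejected)
    patterns: dict[str, list[PlantedPosition]]  # category -> planted positions
    seed_ids: dict[str, list[str]] = field(default_factory=dict)


def _draw_row(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    subgroup: str | None,
) -> str:
    """One aligned sequence; `subgroup` None means a decoy."""
    hp = spec.hyperpartition
    bg = spec.background
    chars = [
        AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=bg)]
        for _ in range(spec.length)
    ]
    if subgroup is None:
        return "".join(chars)
    i = hp.row_index(subgroup)
    for cat, positions in spec.planted.items():
        j = hp.category_names.index(cat)
        cell = hp.cell(i, j)
        if cell == FG:
            p_set = spec.fg_conservation
        elif cell == BG:
            p_set = spec.bg_set_freq
        else:
            p_set = _pooled_rate(spec, cat)
        for pos in positions:
            members = sorted(pos.residues)
            member_idx = [AMINO_ACIDS.index(r) for r in members]
            if rng.random() < p_set:
                chars[pos.column] = members[rng.choice(len(members))]
            else:
                # draw from background renormalized over non-set residues,
                # so the realized set frequency is exactly p_set in expectation
                probs = bg.copy()
                probs[member_idx] = 0.0
                probs /= probs.sum()
                chars[pos.column] = AMINO_ACIDS[
                    rng.choice(len(AMINO_ACIDS), p=probs)
                ]
    return "".join(chars)


def _pooled_rate(spec: SyntheticSpec, cat: str) -> float:
    """Set frequency for omitted subgroups: participant-weighted average."""
    hp = spec.hyperpartition
    j = hp.category_names.index(cat)
    n_fg = n_bg = 0
    for name, n in spec.seqs_per_subgroup.items():
        cell = hp.cell(hp.row_index(name), j)
        if cell == FG:
            n_fg += n
        elif cell == BG:
            n_bg += n
    total = n_fg + n_bg
    if total == 0:
        return spec.bg_set_freq
    return (n_fg * spec.fg_conservation + n_bg * spec.bg_set_freq) / total


def generate(
    spec: SyntheticSpec,
) -> tuple[MSA, list[SeedAlignment], Truth]:
    """Generate the alignment, per-subgroup seed alignments, and the truth.

    The first ``seeds_per_subgroup`` sequences of each subgroup form its seed
    alignment. Decoys are named ``decoy###`` with truth subgroup Rejected.
    Duplicates are byte-copies of round-robin subgroup members; fragments
    are members with all but a quarter of their columns gapped out.
    """
    rng = np.random.default_rng(spec.rng_seed)
    ids: list[str] = []
    rows: list[str] = []
    truth_assign: dict[str, str] = {}
    seed_ids: dict[str, list[str]] = {}

    subgroups = [
        name
        for name in spec.hyperpartition.subgroup_names
        if name in spec.seqs_per_subgroup
    ]
    for name in subgroups:
        seed_ids[name] = []
        for k in range(spec.seqs_per_subgroup[name]):
            sid = f"{name}_{k:03d}"
            ids.append(sid)
            rows.append(_draw_row(rng, spec, name))
            truth_assign[sid] = name
            if k < spec.seeds_per_subgroup:
                seed_ids[name].append(sid)

    for k in range(spec.n_decoys):
        sid = f"decoy{k:03d}"
        ids.append(sid)
        rows.append(_draw_row(rng, spec, None))
        truth_assign[sid] = REJECTED

    originals = [
        (sid, row)
        for sid, row in zip(ids, rows)
        if truth_assign[sid] != REJECTED
    ]
    for k in range(spec.n_duplicates):
        src_id, src_row = originals[k % len(originals)]
        sid = f"dup{k:03d}_of_{src_id}"
        ids.append(sid)
        rows.append(src_row)
        truth_assign[sid] = truth_assign[src_id]
    for k in range(spec.n_fragments):
        src_id, src_row = originals[(k + 1) % len(originals)]
        keep = max(1, spec.length // 4)
        frag = "-" * (spec.length - keep) + src_row[spec.length - keep:]
        sid = f"frag{k:03d}_of_{src_id}"
        ids.append(sid)
        rows.append(frag)
        truth_assign[sid] = truth_assign[src_id]

    msa = MSA(ids, rows)
    seeds = [
        SeedAlignment(name, msa.subset(seed_ids[name]))
        for name in subgroups
        if seed_ids[name]
    ]
    truth = Truth(truth_assign, dict(spec.planted), seed_ids)
    return msa, seeds, truth


def emit(
    spec: SyntheticSpec, outdir: str | Path
) -> tuple[Path, Path, dict[str, Path], Path]:
    """Write alignment, hyperpartition, per-subgroup seed FASTAs, truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    msa, seeds, truth = generate(spec)
    aln_path = outdir / "alignment.fasta"
    write_alignment(msa, aln_path)
    hp_path = outdir / "hyperpartition.tsv"
    write_hyperpartition(spec.hyperpartition.with_rejected_row(), hp_path)
    seed_dir = outdir / "seeds"
    seed_dir.mkdir(exist_ok=True)
    seed_paths = {}
    for seed in seeds:
        p = seed_dir / f"{seed.subgroup_name}.fasta"
        write_alignment(seed.msa, p)
        seed_paths[seed.subgroup_name] = p
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("id\tsubgroup\n")
        for sid, sub in truth.assignment.items():
            fh.write(f"{sid}\t{sub}\n")
    return aln_path, hp_path, seed_paths, truth_path


def leaf_contrast_hyperpartition(names: list[str]) -> Hyperpartition:
    """One-vs-rest scheme: category i has subgroup i foreground, others
    background; a Rejected row is appended."""
    n = len(names)
    cells = [
        "".join(FG if i == j else BG for j in range(n)) for i in range(n)
    ]
    hp = Hyperpartition(list(names), list(names), cells)
    return hp.with_rejected_row()


def standard_fixture_spec(
    rng_seed: int = 1,
    n_subgroups: int = 3,
    seqs_per_subgroup: int = 100,
    n_decoys: int = 30,
    planted_per_category: int = 10,
    length: int = 200,
    fg_conservation: float = 0.9,
    bg_set_freq: float = 0.1,
    n_duplicates: int = 0,
    n_fragments: int = 0,
) -> SyntheticSpec:
    """The standard recovery fixture: one-vs-rest subgroups with planted
    discriminating columns, plus composition-only decoys."""
    names = [f"SG{i + 1}" for i in range(n_subgroups)]
    hp = leaf_contrast_hyperpartition(names)
    rng = np.random.default_rng(rng_seed + 10_000)
    all_cols = rng.permutation(length)[: n_subgroups * planted_per_category]
    planted: dict[str, list[PlantedPosition]] = {}
    for i, name in enumerate(names):
        cols = all_cols[i * planted_per_category : (i + 1) * planted_per_category]
        positions = []
        for c in cols:
            size = int(rng.integers(1, 3))  # singleton or pair residue sets
            members = rng.choice(len(AMINO_ACIDS), size=size, replace=False)
            positions.append(
                PlantedPosition(
                    int(c), frozenset(AMINO_ACIDS[a] for a in members)
                )
            )
        planted[name] = positions
    return SyntheticSpec(
        hyperpartition=hp,
        seqs_per_subgroup={n: seqs_per_subgroup for n in names},
        length=length,
        planted=planted,
        fg_conservation=fg_conservation,
        bg_set_freq=bg_set_freq,
        n_decoys=n_decoys,
        n_duplicates=n_duplicates,
        n_fragments=n_fragments,
        rng_seed=rng_seed,
    )
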