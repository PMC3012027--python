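"""Aligned-FASTA I/O and the in-memory multiple sequence alignment container.

All sequence I/O in the package goes through aligned FASTA: every record has
the same length, gaps are ``'-'``. On input, lowercase is uppercased, ``'.'``
gaps become ``'-'``, and any character outside the 20 canonical amino acids
is mapped to the unknown symbol ``'X'`` ('X' never matches a pattern residue
set, so unknowns are conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: canonical amino acids, in the fixed code order used throughout the package
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN = "X"
GAP = "-"
#: full alphabet; integer codes are indices into this string
ALPHABET = AMINO_ACIDS + UNKNOWN + GAP
AA_CODES = {c: i for i, c in enumerate(ALPHABET)}
N_AA = len(AMINO_ACIDS)
X_CODE = AA_CODES[UNKNOWN]
GAP_CODE = AA_CODES[GAP]

_NORMALIZE = {}
for _c in ALPHABET:
    _NORMALIZE[_c] = _c
    _NORMALIZE[_c.lower()] = _c
_NORMALIZE["."] = GAP


def normalize_residues(s: str) -> str:
    """Uppercase, map '.' to '-', and map unknown characters to 'X'."""
    return "".join(_NORMALIZE.get(c, UNKNOWN) for c in s)


class MSAError(ValueError):
    pass


@dataclass
class MSA:
    """An equal-length protein alignment with optional redundancy weights.

    Weights, when present, are positive and rescaled to mean 1 (so their sum
    equals the number of sequences); they carry PSI-BLAST-style redundancy
    down-weighting (see :mod:`mcbpps.preprocess`).
    """

    ids: list[str]
    rows: list[str]
    weights: np.ndarray | None = None
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise MSAError("ids and rows differ in length")
        if len(self.ids) == 0:
            raise MSAError("no sequences")
        if len(set(self.ids)) != len(self.ids):
            dup = next(i for i in self.ids if self.ids.count(i) > 1)
            raise MSAError(f"duplicate identifier: {dup!r}")
        L = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise MSAError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(row)}, expected {L}"
                )
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.ids),):
                raise MSAError("weights shape mismatch")
            if not np.all(w > 0):
                raise MSAError("weights must be positive")
            self.weights = w

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def matrix(self) -> np.ndarray:
        """Integer-coded residues, shape (n, length), codes index ALPHABET."""
        if self._matrix is None:
            buf = np.frombuffer(
                "".join(self.rows).encode("ascii"), dtype=np.uint8
            ).reshape(self.n, self.length)
            lut = np.full(128, X_CODE, dtype=np.uint8)
            for c, code in AA_CODES.items():
                lut[ord(c)] = code
            self._matrix = lut[buf]
        return self._matrix

    def index_of(self, sid: str) -> int:
        try:
            return self.ids.index(sid)
        except ValueError:
            raise KeyError(f"unknown sequence id: {sid!r}") from None

    def subset(self, ids: Iterable[str]) -> "MSA":
        """New MSA restricted to `ids`, preserving this alignment's order."""
        wanted = set(ids)
        unknown = wanted - set(self.ids)
        if unknown:
            raise KeyError(f"unknown sequence ids: {sorted(unknown)}")
        keep = [i for i, sid in enumerate(self.ids) if sid in wanted]
        w = self.weights[keep] if self.weights is not None else None
        return MSA([self.ids[i] for i in keep], [self.rows[i] for i in keep], w)

    def with_weights(self, weights: np.ndarray) -> "MSA":
        return MSA(list(self.ids), list(self.rows), np.asarray(weights, float))


@dataclass
class SeedAlignment:
    """A small curated alignment anchoring one subgroup.

    Seed sequences are fixed to their subgroup throughout sampling and act as
    a Bayesian prior on subgroup membership. A seed may be a single consensus
    sequence. Columns must match the main alignment.
    """

    subgroup_name: str
    msa: MSA
    is_consensus: bool = False

    def check_against(self, main: MSA) -> None:
        if self.msa.length != main.length:
            raise MSAError(
                f"seed alignment {self.subgroup_name!r} has {self.msa.length} "
                f"columns, main alignment has {main.length}"
            )


def read_alignment(path: str | Path) -> MSA:
    """Read an aligned FASTA file into an :class:`MSA`.

    Residues are normalized (uppercase, '.'->'-', unknowns->'X'). Raises
    :class:`MSAError` on an empty file, ragged records, or duplicate ids.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MSAError(f"no sequences in {path}")
    ids = [r.id for r in records]
    rows = [normalize_residues(str(r.seq)) for r in records]
    return MSA(ids, rows)


def write_alignment(msa: MSA, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(msa.ids, msa.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_seed_alignment(path: str | Path, subgroup_name: str) -> SeedAlignment:
    name = str(path)
    is_consensus = "consensus" in Path(path).stem.lower()
    return SeedAlignment(subgroup_name, read_alignment(name), is_consensus)


def write_subgroup_fastas(
    msa: MSA, assignment: Mapping[str, str], outdir: str | Path
) -> dict[str, Path]:
    """Write one aligned FASTA per subgroup, input order preserved.

    Every id in `assignment` must exist in `msa`. A subgroup with no assigned
    sequences yields a file with zero records. Returns subgroup -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    known = set(msa.ids)
    for sid in assignment:
        if sid not in known:
            raise KeyError(f"unknown sequence id in assignment: {sid!r}")
    paths: dict[str, Path] = {}
    for subgroup in dict.fromkeys(assignment.values()):
        paths[subgroup] = outdir / f"{subgroup}.fasta"
    by_group: dict[str, list[SeqRecord]] = {g: [] for g in paths}
    for sid, row in zip(msa.ids, msa.rows):
        g = assignment.get(sid)
        if g is not None:
            by_group[g].append(SeqRecord(Seq(row), id=sid, description=""))
    for g, recs in by_group.items():
        SeqIO.write(recs, str(paths[g]), "fasta")
    return paths
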