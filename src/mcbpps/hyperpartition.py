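"""The hyperpartition: an N x M table of '+'/'-'/'o' cells.

Each of the N rows is a protein subgroup; each of the M columns is one
foreground-vs-background contrast (a category). Cell (i, j) assigns subgroup
i to the foreground ('+'), background ('-'), or non-participating ('o')
partition of category j. A rooted phylogenetic tree maps onto a
hyperpartition: one row and one column per node, where row i is '+' in
column j if node i lies in the subtree rooted at j, '-' if it lies in a
sibling subtree of j, and 'o' otherwise. Internal-node rows are
"miscellaneous" subgroups — clade members claimed by no leaf subfamily.

A designated Rejected row (the random-sequence sink for pseudogene products
and other aberrant sequences) carries no foreground assignment; in a
tree-derived scheme it serves as the background of the root category, which
contrasts the whole family against random sequences.

Validity rules:
  * every non-rejected row has at least one '+' cell;
  * no two rows share an identical set of '+' columns;
  * M >= N, counting neither the rejected row (it defines no category);
  * every category has at least one '+' row and at least one '-' row;
  * the rejected row, if present, has no '+' cell.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy

FG, BG, OMIT = "+", "-", "o"
SYMBOLS = {FG, BG, OMIT}
REJECTED = "Rejected"


class HyperpartitionError(ValueError):
    pass


@dataclass
class Hyperpartition:
    subgroup_names: list[str]
    category_names: list[str]
    cells: list[str]  # one string of length M per subgroup
    misc_flags: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.misc_flags:
            self.misc_flags = [False] * len(self.subgroup_names)
        if len({*self.subgroup_names}) != len(self.subgroup_names):
            raise HyperpartitionError("duplicate subgroup name")
        if len(self.cells) != len(self.subgroup_names):
            raise HyperpartitionError("one cell row required per subgroup")
        M = len(self.category_names)
        for name, row in zip(self.subgroup_names, self.cells):
            if len(row) != M:
                raise HyperpartitionError(f"ragged row for subgroup {name!r}")
            bad = set(row) - SYMBOLS
            if bad:
                col = next(k for k, c in enumerate(row) if c in bad)
                raise HyperpartitionError(
                    f"invalid symbol {row[col]!r} at subgroup {name!r}, "
                    f"category {self.category_names[col]!r}"
                )

    @property
    def n_subgroups(self) -> int:
        return len(self.subgroup_names)

    @property
    def n_categories(self) -> int:
        return len(self.category_names)

    @property
    def rejected_index(self) -> int | None:
        try:
            return self.subgroup_names.index(REJECTED)
        except ValueError:
            return None

    def row_index(self, name: str) -> int:
        try:
            return self.subgroup_names.index(name)
        except ValueError:
            raise KeyError(f"unknown subgroup: {name!r}") from None

    def cell(self, i: int, j: int) -> str:
        return self.cells[i][j]

    def fg_signature(self, i: int) -> frozenset[int]:
        return frozenset(j for j, c in enumerate(self.cells[i]) if c == FG)

    def with_rejected_row(self) -> "Hyperpartition":
        """Return self, or a copy with an all-OMIT Rejected row appended."""
        if self.rejected_index is not None:
            return self
        return Hyperpartition(
            self.subgroup_names + [REJECTED],
            list(self.category_names),
            self.cells + [OMIT * self.n_categories],
            self.misc_flags + [False],
        )


def validate(hp: Hyperpartition) -> list[str]:
    """Return the list of violated validity rules (empty means valid)."""
    violations: list[str] = []
    rej = hp.rejected_index
    signatures: dict[frozenset[int], str] = {}
    for i, name in enumerate(hp.subgroup_names):
        sig = hp.fg_signature(i)
        if i == rej:
            if sig:
                violations.append("rejected row has a foreground cell")
            continue
        if not sig:
            violations.append(f"row lacks foreground: {name!r}")
            continue
        if sig in signatures:
            violations.append(
                f"duplicate foreground signature: {signatures[sig]!r} and {name!r}"
            )
        else:
            signatures[sig] = name
    n_modeled = hp.n_subgroups - (1 if rej is not None else 0)
    if hp.n_categories < n_modeled:
        violations.append(
            f"fewer categories ({hp.n_categories}) than subgroups ({n_modeled})"
        )
    for j, cname in enumerate(hp.category_names):
        col = [hp.cell(i, j) for i in range(hp.n_subgroups)]
        if FG not in col:
            violations.append(f"category lacks foreground: {cname!r}")
        if BG not in col:
            violations.append(f"category lacks background: {cname!r}")
    return violations


def category_partitions(
    hp: Hyperpartition, j: int
) -> tuple[set[int], set[int], set[int]]:
    """Row-index sets (foreground, background, omitted) of category j."""
    if not (0 <= j < hp.n_categories):
        raise IndexError(f"category index {j} out of range")
    fg = {i for i in range(hp.n_subgroups) if hp.cell(i, j) == FG}
    bg = {i for i in range(hp.n_subgroups) if hp.cell(i, j) == BG}
    om = {i for i in range(hp.n_subgroups) if hp.cell(i, j) == OMIT}
    return fg, bg, om


# ---------------------------------------------------------------------------
# tree conversion


def _tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=False
    )
    return tree


def _node_label(node: dendropy.Node, k: int) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return f"node{k}"


def from_tree(tree: dendropy.Tree | str) -> Hyperpartition:
    """Convert a rooted, labeled tree into its hyperpartition.

    One row and one column per node (preorder). Cell (i, j) is '+' if node i
    is in the subtree of node j, '-' if it is in a sibling subtree of node j,
    'o' otherwise. Internal-node rows are flagged miscellaneous; a Rejected
    row is appended that is background in the root's column (family versus
    random sequences) and omitted elsewhere.
    """
    if isinstance(tree, str):
        tree = _tree_from_newick(tree)
    nodes = list(tree.preorder_node_iter())
    if len(nodes) < 2:
        raise HyperpartitionError(
            "tree must have at least two nodes (a lone root has no sibling "
            "subtree to contrast)"
        )
    labels = [_node_label(nd, k) for k, nd in enumerate(nodes)]
    if len(set(labels)) != len(labels):
        raise HyperpartitionError("tree node labels are not unique")
    index = {id(nd): k for k, nd in enumerate(nodes)}

    # descendants[j] = set of node indices in the subtree rooted at j
    descendants: list[set[int]] = [set() for _ in nodes]
    for nd in tree.postorder_node_iter():
        k = index[id(nd)]
        descendants[k].add(k)
        for ch in nd.child_nodes():
            descendants[k] |= descendants[index[id(ch)]]

    cells = []
    for i in range(len(nodes)):
        row = []
        for j, nd_j in enumerate(nodes):
            if i in descendants[j]:
                row.append(FG)
            else:
                parent = nd_j.parent_node
                in_sibling = parent is not None and any(
                    i in descendants[index[id(sib)]]
                    for sib in parent.child_nodes()
                    if sib is not nd_j
                )
                row.append(BG if in_sibling else OMIT)
        cells.append("".join(row))

    misc = [len(nd.child_nodes()) > 0 for nd in nodes]
    root_col = index[id(tree.seed_node)]
    rejected_row = "".join(
        BG if j == root_col else OMIT for j in range(len(nodes))
    )
    return Hyperpartition(
        labels + [REJECTED],
        list(labels),
        cells + [rejected_row],
        misc + [False],
    )


# ---------------------------------------------------------------------------
# file format
#
# Line 1: tab-separated category names. Each further line: subgroup name,
# TAB, a string of M characters over {+,-,o}. A name suffixed "!misc" marks
# a miscellaneous subgroup. The Rejected row, if present, is last.


def write_hyperpartition(hp: Hyperpartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(hp.category_names) + "\n")
        for name, row, misc in zip(hp.subgroup_names, hp.cells, hp.misc_flags):
            tag = "!misc" if misc else ""
            fh.write(f"{name}{tag}\t{row}\n")


def read_hyperpartition(path: str | Path) -> tuple[Hyperpartition, list[str]]:
    """Parse a hyperpartition file; returns (hyperpartition, warnings).

    Warnings are validity violations — reported, not raised, so a scheme can
    be inspected before repair. Format errors (bad symbols, ragged rows) do
    raise.
    """
    text = Path(path).read_text()
    lines = [ln for ln in io.StringIO(text) if ln.strip()]
    if not lines:
        raise HyperpartitionError(f"empty hyperpartition file: {path}")
    categories = lines[0].rstrip("\n").split("\t")
    names: list[str] = []
    cells: list[str] = []
    misc: list[bool] = []
    for ln in lines[1:]:
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise HyperpartitionError(f"malformed row: {ln.rstrip()!r}")
        name, row = parts
        if name.endswith("!misc"):
            name = name[: -len("!misc")]
            misc.append(True)
        else:
            misc.append(False)
        if len(row) != len(categories):
            raise HyperpartitionError(
                f"ragged row for subgroup {name!r}: {len(row)} cells, "
                f"{len(categories)} categories"
            )
        for k, c in enumerate(row):
            if c not in SYMBOLS:
                raise HyperpartitionError(
                    f"invalid symbol {c!r} at subgroup {name!r}, "
                    f"category {categories[k]!r}"
                )
        names.append(name)
        cells.append(row)
    hp = Hyperpartition(names, categories, cells, misc)
    return hp, validate(hp)
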