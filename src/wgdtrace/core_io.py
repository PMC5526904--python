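"""Sequence, alignment, tree and annotation data model with standard-format I/O.

The containers here are deliberately small: a :class:`SequenceRecord` is an
(id, seq, moltype) triple; an :class:`Alignment` is an ordered, rectangular
collection of gapped records; a :class:`CodonAlignment` additionally promises
in-frame coding sequence (length divisible by 3, gaps in whole-codon units,
no internal stop codons). Trees are parsed with dendropy and re-wrapped into
a light :class:`GeneTree` whose branches can carry class labels (foreground /
background marks, clade partitions) in the codeml ``#1`` / ``$1`` style or
from a sidecar branch->class TSV.

Back-translation threads an unaligned CDS through a protein alignment so that
every residue column becomes one codon triple — the protein-guided codon
alignment construction used upstream of all dN/dS work.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codons import get_code

GAP = "-"

__all__ = [
    "SequenceRecord",
    "Alignment",
    "CodonAlignment",
    "GeneTree",
    "TreeNode",
    "DomainPartition",
    "BacktranslationError",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "write_phylip",
    "read_newick",
    "write_newick",
    "read_gene_loci",
    "backtranslate_alignment",
    "map_residue_ranges",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named residue sequence (protein or DNA; IUPAC ambiguity allowed)."""

    id: str
    seq: str
    moltype: str = "protein"  # {"protein", "dna"}

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.moltype not in ("protein", "dna"):
            raise ValueError(f"unknown moltype {self.moltype!r}")

    @property
    def ungapped(self) -> str:
        return self.seq.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.seq)


class Alignment:
    """An ordered multiple alignment; all rows equal length, gap char '-'."""

    moltype = "protein"

    def __init__(self, records: Iterable[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment needs at least one record")
        length = len(records[0].seq)
        ids = set()
        for r in records:
            if len(r.seq) != length:
                raise ValueError(
                    f"row {r.id!r} has length {len(r.seq)}, expected {length}"
                )
            if r.id in ids:
                raise ValueError(f"duplicate id {r.id!r} in alignment")
            ids.add(r.id)
        self.records: list[SequenceRecord] = records
        self.moltype = records[0].moltype

    def __len__(self) -> int:
        return len(self.records[0].seq)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def __contains__(self, rec_id: str) -> bool:
        return any(r.id == rec_id for r in self.records)

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """Column subset (0-based indices), preserving row order."""
        recs = [
            replace(r, seq="".join(r.seq[c] for c in columns)) for r in self.records
        ]
        return type(self)(recs) if type(self) is Alignment else Alignment(recs)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        recs = [self[i] for i in wanted]
        out = object.__new__(type(self))
        Alignment.__init__(out, recs)
        if isinstance(out, CodonAlignment):
            out.genetic_code = getattr(self, "genetic_code", 1)
        return out


class CodonAlignment(Alignment):
    """In-frame coding alignment: length % 3 == 0, whole-codon gaps, no
    internal stops; ambiguous (N-containing) codons allowed as missing data."""

    moltype = "dna"

    def __init__(self, records: Iterable[SequenceRecord], genetic_code: int = 1):
        super().__init__(records)
        self.genetic_code = genetic_code
        code = get_code(genetic_code)
        if len(self) % 3 != 0:
            raise ValueError(f"codon alignment length {len(self)} not divisible by 3")
        for r in self.records:
            for k in range(0, len(r.seq), 3):
                codon = r.seq[k : k + 3].upper().replace("U", "T")
                n_gap = codon.count(GAP)
                if n_gap not in (0, 3):
                    raise ValueError(
                        f"{r.id!r}: partial-codon gap {codon!r} at codon {k // 3 + 1}"
                    )
                if n_gap == 0 and code.is_stop(codon):
                    raise ValueError(
                        f"{r.id!r}: internal stop codon {codon!r} at codon {k // 3 + 1}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self) // 3

    def codons_of(self, rec_id: str) -> list[str]:
        s = self[rec_id].seq
        return [s[k : k + 3] for k in range(0, len(s), 3)]

    def take_codon_columns(self, codon_columns: Sequence[int]) -> "CodonAlignment":
        """Subset by 0-based codon-column indices."""
        cols = [c * 3 + o for c in codon_columns for o in range(3)]
        recs = [
            replace(r, seq="".join(r.seq[c] for c in cols)) for r in self.records
        ]
        return CodonAlignment(recs, genetic_code=self.genetic_code)

    def translate(self) -> Alignment:
        """Per-row translation; gap codons become '-', ambiguous codons 'X'."""
        code = get_code(self.genetic_code)
        out = []
        for r in self.records:
            aas = []
            for k in range(0, len(r.seq), 3):
                codon = r.seq[k : k + 3]
                aas.append(GAP if codon == GAP * 3 else code.translate(codon))
            out.append(SequenceRecord(r.id, "".join(aas), "protein"))
        return Alignment(out)


@dataclass(frozen=True)
class DomainPartition:
    """A named 1-based inclusive residue range on a reference sequence."""

    name: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"partition {self.name!r}: invalid range {self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """One node of a :class:`GeneTree`; ``length``/``branch_class`` describe
    the edge to the parent."""

    name: str | None = None
    length: float | None = None
    branch_class: int = 0
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GeneTree:
    """Rooted-representation tree with optional branch lengths and integer
    branch-class labels (0 = background; ``#k`` marks class k)."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [n.name for n in self.leaves()]
        if len(names) != len(set(names)):
            raise ValueError("leaf names must be unique")
        for node in self.postorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on {node.name!r}")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def rec(n: TreeNode):
            for c in n.children:
                rec(c)
            out.append(n)

        rec(self.root)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branch_classes(self) -> set[int]:
        return {n.branch_class for n in self.postorder() if n.parent is not None}

    def set_branch_classes(self, class_map: Mapping[str, int]) -> None:
        """Assign classes from a {leaf-or-internal-node-name: class} map; a
        named internal node labels its subtending branch only."""
        for node in self.postorder():
            if node.name is not None and node.name in class_map:
                node.branch_class = int(class_map[node.name])

    def label_clade(self, leaf_names: Iterable[str], branch_class: int,
                    stem: bool = True) -> None:
        """Label every branch inside the clade spanned by ``leaf_names``
        (optionally including the stem branch) with ``branch_class``."""
        wanted = set(leaf_names)

        def rec(n: TreeNode) -> set[str]:
            if n.is_leaf:
                below = {n.name}
            else:
                below = set()
                for c in n.children:
                    below |= rec(c)
            if below and below.issubset(wanted):
                n.branch_class = branch_class
            return below

        rec(self.root)
        if not stem:
            # undo the label on the shallowest fully-contained node
            for node in self.postorder():
                kids = set(l.name for l in _subtree_leaves(node))
                if kids == wanted:
                    node.branch_class = 0
                    break

    def copy(self) -> "GeneTree":
        def rec(n: TreeNode, parent=None) -> TreeNode:
            m = TreeNode(name=n.name, length=n.length, branch_class=n.branch_class,
                         parent=parent)
            m.children = [rec(c, m) for c in n.children]
            return m

        return GeneTree(rec(self.root))

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n.parent is not None)

    def extract_subtree(self, leaf_names: Iterable[str]) -> "GeneTree":
        """Subtree induced by a leaf subset, suppressing unary nodes (their
        branch lengths are summed)."""
        wanted = set(leaf_names)
        missing = wanted - set(self.leaf_names)
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")

        def rec(n: TreeNode) -> TreeNode | None:
            if n.is_leaf:
                if n.name in wanted:
                    return TreeNode(name=n.name, length=n.length,
                                    branch_class=n.branch_class)
                return None
            kept = [k for k in (rec(c) for c in n.children) if k is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if child.length is not None and n.length is not None:
                    child.length += n.length
                elif child.length is None:
                    child.length = n.length
                return child
            m = TreeNode(name=n.name, length=n.length, branch_class=n.branch_class)
            m.children = kept
            for k in kept:
                k.parent = m
            return m

        root = rec(self.root)
        if root is None:
            raise ValueError("empty leaf selection")
        root.length = None
        return GeneTree(root)


def _subtree_leaves(node: TreeNode) -> list[TreeNode]:
    if node.is_leaf:
        return [node]
    out = []
    for c in node.children:
        out.extend(_subtree_leaves(c))
    return out


_MARK_RE = re.compile(r"\s*([#$])(\d+)")


def read_newick(source: str | Path, branch_class_tsv: str | Path | None = None
                ) -> GeneTree:
    """Parse a Newick tree; codeml-style ``#k`` / ``$k`` branch marks are
    extracted before parsing and re-attached as integer branch classes.
    A sidecar TSV (node-name <tab> class) may supply classes instead."""
    text = Path(source).read_text() if _looks_like_path(source) else str(source)

    def stash(m: re.Match) -> str:
        # '#k' marks one branch, '$k' a whole clade; encode both in the label
        kind = "C" if m.group(1) == "$" else "B"
        return f"__MARK{kind}{int(m.group(2))}__"

    text = _MARK_RE.sub(stash, text)

    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=False,
                              preserve_underscores=True)

    clade_marked: list[TreeNode] = []

    def convert(dnode, parent=None) -> TreeNode:
        raw = dnode.taxon.label if dnode.taxon else dnode.label
        cls, is_clade, name = 0, False, raw
        if raw:
            m = re.search(r"__MARK([CB])(\d+)__", raw)
            if m:
                cls = int(m.group(2))
                is_clade = m.group(1) == "C"
                name = re.sub(r"__MARK[CB]\d+__", "", raw) or None
        node = TreeNode(name=name, length=dnode.edge.length, branch_class=cls,
                        parent=parent)
        if is_clade:
            clade_marked.append(node)
        node.children = [convert(c, node) for c in dnode.child_nodes()]
        return node

    tree = GeneTree(convert(dtree.seed_node))
    # a "$k" clade mark propagates to all unlabeled descendant branches
    for node in clade_marked:
        _propagate_class(node)
    if branch_class_tsv is not None:
        class_map = {}
        for line in Path(branch_class_tsv).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, cls = line.split("\t")[:2]
            class_map[name] = int(cls)
        tree.set_branch_classes(class_map)
    return tree


def _propagate_class(node: TreeNode) -> None:
    for c in node.children:
        if c.branch_class == 0:
            c.branch_class = node.branch_class
            _propagate_class(c)


def _looks_like_path(source) -> bool:
    if isinstance(source, Path):
        return True
    s = str(source)
    return "(" not in s and (s.endswith((".nwk", ".tree", ".newick", ".txt"))
                             or Path(s).exists())


def write_newick(tree: GeneTree, path: str | Path | None = None,
                 marks: bool = True) -> str:
    """Serialize to Newick; non-zero branch classes re-emitted as ``#k``."""

    def rec(n: TreeNode) -> str:
        if n.is_leaf:
            s = n.name or ""
        else:
            s = "(" + ",".join(rec(c) for c in n.children) + ")" + (n.name or "")
        if marks and n.parent is not None and n.branch_class != 0:
            s += f" #{n.branch_class}"
        if n.length is not None:
            s += f":{n.length:.10g}"
        return s

    text = rec(tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# FASTA / PHYLIP / gene loci
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, moltype: str = "protein") -> list[SequenceRecord]:
    return [
        SequenceRecord(rec.id, str(rec.seq), moltype)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord] | Alignment,
                path: str | Path) -> None:
    if isinstance(records, Alignment):
        records = records.records
    seqs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_alignment(path: str | Path, moltype: str = "protein") -> Alignment:
    return Alignment(read_fasta(path, moltype))


def read_codon_alignment(path: str | Path, genetic_code: int = 1) -> CodonAlignment:
    return CodonAlignment(read_fasta(path, "dna"), genetic_code=genetic_code)


def write_phylip(aln: Alignment, path: str | Path) -> None:
    """Sequential PHYLIP (relaxed names: name, two spaces, sequence)."""
    with open(path, "w") as fh:
        fh.write(f" {aln.n_rows} {len(aln)}\n")
        for r in aln.records:
            fh.write(f"{r.id}  {r.seq}\n")


def read_gene_loci(path: str | Path, fmt: str | None = None):
    """Read gene loci from BED6 or GFF3 into a list of (gene_id, chrom,
    start, strand) tuples sorted by (chrom, start); the synteny module turns
    these into rank-ordered loci."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    rows = []
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if fmt == "bed":
            chrom, start, _end, name, _score, strand = f[:6]
            rows.append((name, chrom, int(start), strand))
        else:
            if f[2].lower() != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
            rows.append((name, f[0], int(f[3]), f[6]))
    rows.sort(key=lambda r: (r[1], r[2]))
    return rows


# ---------------------------------------------------------------------------
# Back-translation and domain mapping
# ---------------------------------------------------------------------------


class BacktranslationError(ValueError):
    pass


def backtranslate_alignment(
    protein_aln: Alignment,
    cds: Mapping[str, SequenceRecord] | Iterable[SequenceRecord],
    genetic_code: int = 1,
) -> CodonAlignment:
    """Thread unaligned CDS through a protein alignment, codon by codon.

    Every residue column becomes one codon triple and every protein gap
    becomes ``---``. The CDS must be exactly 3x the ungapped residue count,
    optionally +3 for a terminal stop codon (stripped). Each codon is
    verified to translate to its aligned residue; a mismatch is fatal and
    reported at its 1-based residue index.
    """
    if not isinstance(cds, Mapping):
        cds = {r.id: r for r in cds}
    code = get_code(genetic_code)
    out = []
    for row in protein_aln.records:
        if row.id not in cds:
            raise BacktranslationError(f"missing CDS for {row.id!r}")
        nt = cds[row.id].seq.upper().replace("U", "T").replace(GAP, "")
        n_res = len(row.ungapped)
        if len(nt) == 3 * n_res + 3 and code.is_stop(nt[-3:]):
            nt = nt[:-3]  # strip terminal stop
        if len(nt) != 3 * n_res:
            raise BacktranslationError(
                f"{row.id!r}: CDS length {len(nt)} does not match "
                f"3 x {n_res} residues"
            )
        codons = []
        k = 0
        for res_i, residue in enumerate(row.seq):
            if residue == GAP:
                codons.append(GAP * 3)
                continue
            codon = nt[3 * k : 3 * k + 3]
            k += 1
            if code.is_stop(codon):
                raise BacktranslationError(
                    f"{row.id!r}: internal stop codon {codon} at residue {k}"
                )
            aa = code.translate(codon)
            if residue.upper() != aa and residue.upper() != "X" and aa != "X":
                raise BacktranslationError(
                    f"{row.id!r}: translation mismatch at residue {k} "
                    f"(expected {residue.upper()}, codon {codon}={aa})"
                )
            codons.append(codon)
        out.append(SequenceRecord(row.id, "".join(codons), "dna"))
    return CodonAlignment(out, genetic_code=genetic_code)


def residue_columns_for_range(
    aln: Alignment, reference_id: str, partition: DomainPartition
) -> list[int]:
    """0-based alignment columns whose *reference* ungapped residue index
    (1-based) lies in the partition range."""
    ref = aln[reference_id]
    n_res = len(ref.ungapped)
    if partition.end > n_res:
        raise ValueError(
            f"partition {partition.name!r} range {partition.start}-{partition.end} "
            f"exceeds reference length {n_res}"
        )
    cols = []
    res_i = 0
    for col, ch in enumerate(ref.seq):
        if ch == GAP:
            continue
        res_i += 1
        if partition.start <= res_i <= partition.end:
            cols.append(col)
    return cols


def map_residue_ranges(
    codon_aln: CodonAlignment, partition: DomainPartition, reference_id: str
) -> CodonAlignment:
    """Codon-column subset covering a residue range of the reference row,
    mapped through alignment gaps. Ranges are 1-based inclusive in the
    reference's own (ungapped) residue coordinates."""
    if reference_id not in codon_aln:
        raise KeyError(f"reference {reference_id!r} absent from alignment")
    protein_view = codon_aln.translate()
    cols = residue_columns_for_range(protein_view, reference_id, partition)
    return codon_aln.take_codon_columns(cols)
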