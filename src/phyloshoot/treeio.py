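"""File formats and the on-disk database layout.

The tool touches four plain-text formats: FASTA (sequences and alignments),
Newick (gene trees, subtrees, supertrees; bootstrap supports stored as bare
internal-node labels, IQ-TREE style), TSV (gene -> species map, profile
table) and JSON (manifest, build parameters).

Trees are represented as :class:`skbio.TreeNode` objects.  After parsing,
integer internal-node labels are moved onto a ``support`` attribute (0-100,
``None`` where absent) so that tree surgery elsewhere in the package can
treat support as a property of the edge/bipartition rather than of the node
name.  ``write_newick`` reverses the convention, so round-trips are lossless.
"""

from __future__ import annotations

import io
import json
import shutil
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MSA_ALPHABET = frozenset(AMINO_ACIDS) | {"X", GAP}
SEQ_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}

MANIFEST_NAME = "phyloshoot.json"
DB_FORMAT = "phyloshoot-db"


class InputError(ValueError):
    """A malformed or inconsistent user-supplied input."""


class NewickParseError(InputError):
    pass


# ---------------------------------------------------------------------------
# FASTA


class FastaDict(dict):
    """Ordered id -> sequence mapping; header descriptions kept as metadata."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.descriptions: dict[str, str] = {}


def read_fasta(path) -> FastaDict:
    """Read a protein FASTA file.

    Ids are the first whitespace-delimited token of each header; the rest of
    the header is retained in ``result.descriptions``.  Sequences are
    uppercased.  Duplicate ids and empty files are errors.
    """
    path = Path(path)
    records = FastaDict()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise InputError(f"duplicate id {rec.id} in {path}")
            records[rec.id] = str(rec.seq).upper()
            desc = rec.description[len(rec.id):].strip()
            if desc:
                records.descriptions[rec.id] = desc
    if not records:
        raise InputError(f"empty or invalid FASTA file: {path}")
    return records


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=g, description="") for g, s in sequences.items()]
    with open(path, "w") as handle:
        SeqIO.write(recs, handle, "fasta-2line")


# ---------------------------------------------------------------------------
# MSA


class Msa:
    """An ordered gene id -> aligned amino-acid row mapping.

    All rows have equal length; the only gap character is '-'; the residue
    alphabet is the 20 amino acids plus 'X'.
    """

    __slots__ = ("_rows",)

    def __init__(self, rows: Mapping[str, str]):
        rows = {str(k): str(v).upper() for k, v in rows.items()}
        if not rows:
            raise InputError("empty MSA")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise InputError(f"MSA rows have unequal lengths: {sorted(widths)}")
        for gid, row in rows.items():
            bad = set(row) - MSA_ALPHABET
            if bad:
                raise InputError(
                    f"illegal character(s) {sorted(bad)} in MSA row {gid}"
                )
        self._rows = rows

    @property
    def rows(self) -> dict[str, str]:
        return self._rows

    @property
    def ids(self) -> list[str]:
        return list(self._rows)

    @property
    def width(self) -> int:
        return len(next(iter(self._rows.values())))

    def __len__(self) -> int:
        return len(self._rows)

    def __getitem__(self, gid: str) -> str:
        return self._rows[gid]

    def __contains__(self, gid: str) -> bool:
        return gid in self._rows

    def __iter__(self):
        return iter(self._rows)

    def items(self):
        return self._rows.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, Msa) and self._rows == other._rows

    def __repr__(self) -> str:
        return f"<Msa: {len(self)} rows x {self.width} columns>"


def read_msa(path) -> Msa:
    return Msa(read_fasta(path))


def write_msa(path, msa: Msa) -> None:
    write_fasta(path, msa.rows)


# ---------------------------------------------------------------------------
# Newick


def _attach_supports(tree: TreeNode) -> None:
    """Move integer internal-node labels onto ``node.support``."""
    for node in tree.traverse(include_self=True):
        node.support = None
    for node in tree.non_tips(include_self=False):
        name = node.name
        if name is not None:
            try:
                value = int(name)
            except ValueError:
                continue
            if 0 <= value <= 100:
                node.support = value
                node.name = None


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a rooted tree.

    Integer internal-node labels in 0-100 become ``node.support``; missing
    branch lengths default to 0.0 (the root keeps ``length=None``).
    """
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty Newick string")
    if stripped.count("(") != stripped.count(")"):
        raise NewickParseError(
            "unbalanced parentheses in Newick string "
            f"(char offset {min(len(stripped), stripped.rfind('(') + 1)})"
        )
    end = stripped.find(";")
    if end == -1:
        raise NewickParseError(
            f"Newick string not ';'-terminated (char offset {len(stripped)})"
        )
    if stripped[end + 1:].strip():
        raise NewickParseError(
            f"trailing garbage after Newick tree (char offset {end + 1})"
        )
    try:
        tree = TreeNode.read(io.StringIO(stripped), convert_underscores=False)
    except Exception as exc:  # skbio raises NewickFormatError
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    for node in tree.traverse(include_self=True):
        if node.length is None and node.parent is not None:
            node.length = 0.0
        if node.length is not None and node.length < 0:
            raise NewickParseError(
                f"negative branch length {node.length} on node {node.name!r}"
            )
    _attach_supports(tree)
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise NewickParseError(f"duplicate leaf label(s): {dupes}")
    return tree


def read_newick(path) -> TreeNode:
    return parse_newick(Path(path).read_text())


def _fmt_length(x: float | None) -> str:
    if x is None:
        return ""
    return f":{x:.10g}"


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree; supports become bare internal-node labels."""

    def rec(node: TreeNode) -> str:
        if node.is_tip():
            return f"{node.name}{_fmt_length(node.length)}"
        inner = ",".join(rec(c) for c in node.children)
        support = getattr(node, "support", None)
        label = node.name if node.name is not None else (
            str(support) if support is not None else ""
        )
        length = _fmt_length(node.length) if node.parent is not None else ""
        return f"({inner}){label}{length}"

    return rec(tree) + ";"


def save_newick(path, tree: TreeNode) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Tree helpers shared across modules


def tree_copy(tree: TreeNode) -> TreeNode:
    """Deep copy preserving the ``support`` attribute."""
    return parse_newick(write_newick(tree))


def leaf_names(tree: TreeNode) -> list[str]:
    return [t.name for t in tree.tips()]


def validate_gene_tree(tree: TreeNode) -> None:
    names = leaf_names(tree)
    if len(names) != len(set(names)):
        raise InputError("duplicate leaf labels in gene tree")
    for node in tree.non_tips(include_self=False):
        if len(node.children) < 2:
            raise InputError("internal node of degree < 2 in gene tree")
        if node.length is not None and node.length < 0:
            raise InputError("negative branch length in gene tree")


# ---------------------------------------------------------------------------
# Species map


def read_species_map(path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise InputError(
                f"{path}:{lineno}: expected 'gene_id<TAB>species_id', got {line!r}"
            )
        gene, species = parts
        if gene in mapping:
            raise InputError(f"duplicate gene id {gene} in species map")
        mapping[gene] = species
    if not mapping:
        raise InputError(f"empty species map: {path}")
    return mapping


def write_species_map(path, mapping: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for gene, species in mapping.items():
            fh.write(f"{gene}\t{species}\n")


# ---------------------------------------------------------------------------
# Database layout


@dataclass
class DatabaseLayout:
    """Where a built database lives on disk and what it contains."""

    root: Path
    family_ids: list[str]
    params: dict = field(default_factory=dict)

    def family_dir(self, fam: str) -> Path:
        return self.root / "families" / fam

    @property
    def manifest_path(self) -> Path:
        return self.root / MANIFEST_NAME

    @property
    def species_map_path(self) -> Path:
        return self.root / "species_map.tsv"

    @property
    def profile_table_path(self) -> Path:
        return self.root / "profiles.tsv"

    @property
    def profile_fasta_path(self) -> Path:
        return self.root / "profiles.fa"


def save_database(db, path, overwrite: bool = False) -> DatabaseLayout:
    """Write a built in-memory database (see ``dbbuild.Database``) to disk."""
    root = Path(path)
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise InputError(f"output directory {root} exists and is not empty")
        shutil.rmtree(root)
    (root / "families").mkdir(parents=True, exist_ok=True)

    profile_rows: list[tuple[str, str, str]] = []
    profile_seqs: dict[str, str] = {}
    for fam, entry in db.families.items():
        fdir = root / "families" / fam
        fdir.mkdir(parents=True, exist_ok=True)
        group = entry.group
        write_fasta(fdir / "sequences.fa", group.sequences)
        write_msa(fdir / "msa.aln.fa", group.msa)
        save_newick(fdir / "tree.nwk", group.tree)
        split = entry.split
        meta = {
            "is_split": split.is_split,
            "subtrees": [
                {"id": st.subtree_id, "members": st.members, "outgroup": st.outgroup}
                for st in split.subtrees
            ],
        }
        (fdir / "split.json").write_text(json.dumps(meta, indent=1))
        if split.is_split:
            save_newick(fdir / "supertree.nwk", split.supertree)
            sdir = fdir / "subtrees"
            sdir.mkdir(exist_ok=True)
            for st in split.subtrees:
                save_newick(sdir / f"{st.subtree_id}.nwk", st.tree)
                write_msa(sdir / f"{st.subtree_id}.aln.fa", st.msa)
        for sid, reps in entry.representatives.items():
            for rid in reps:
                profile_rows.append((rid, fam, sid))
                profile_seqs[rid] = group.sequences[rid]

    with open(root / "profiles.tsv", "w") as fh:
        for rid, fam, sid in profile_rows:
            fh.write(f"{rid}\t{fam}\t{sid}\n")
    write_fasta(root / "profiles.fa", profile_seqs)
    write_species_map(root / "species_map.tsv", db.species_map)

    layout = DatabaseLayout(
        root=root,
        family_ids=sorted(db.families),
        params=db.config.to_dict(),
    )
    manifest = {
        "format": DB_FORMAT,
        "version": 1,
        "families": layout.family_ids,
        "params": layout.params,
    }
    layout.manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return layout


def load_database(path):
    """Load a database written by :func:`save_database`.

    Returns a ``dbbuild.Database``.
    """
    from . import dbbuild  # late import: dbbuild depends on treeio

    root = Path(path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise InputError(f"{root} is not a phyloshoot database (missing manifest)")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != DB_FORMAT:
        raise InputError(f"{root} is not a phyloshoot database (bad format field)")

    config = dbbuild.BuildConfig.from_dict(manifest["params"])
    species_map = read_species_map(root / "species_map.tsv")

    rep_map: dict[str, dict[str, list[str]]] = {}
    for line in (root / "profiles.tsv").read_text().splitlines():
        if not line.strip():
            continue
        rid, fam, sid = line.split("\t")
        rep_map.setdefault(fam, {}).setdefault(sid, []).append(rid)

    families: dict[str, dbbuild.FamilyEntry] = {}
    for fam in manifest["families"]:
        fdir = root / "families" / fam
        if not fdir.is_dir():
            raise InputError(f"manifest lists family {fam} but {fdir} is missing")
        sequences = read_fasta(fdir / "sequences.fa")
        msa = read_msa(fdir / "msa.aln.fa")
        tree = read_newick(fdir / "tree.nwk")
        group = dbbuild.HomologGroup(fam, dict(sequences), msa, tree)
        meta = json.loads((fdir / "split.json").read_text())
        if meta["is_split"]:
            supertree = read_newick(fdir / "supertree.nwk")
            subtrees = []
            for st in meta["subtrees"]:
                subtrees.append(
                    dbbuild.Subtree(
                        subtree_id=st["id"],
                        members=list(st["members"]),
                        outgroup=st["outgroup"],
                        tree=read_newick(fdir / "subtrees" / f"{st['id']}.nwk"),
                        msa=read_msa(fdir / "subtrees" / f"{st['id']}.aln.fa"),
                    )
                )
            split = dbbuild.SplitFamily(fam, True, subtrees, supertree)
        else:
            st = meta["subtrees"][0]
            split = dbbuild.SplitFamily(
                fam,
                False,
                [dbbuild.Subtree(st["id"], list(st["members"]), None, group.tree, msa)],
                None,
            )
        families[fam] = dbbuild.FamilyEntry(
            group=group, split=split, representatives=rep_map.get(fam, {})
        )
    return dbbuild.Database(config=config, families=families, species_map=species_map)
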