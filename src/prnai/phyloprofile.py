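"""Hierarchical orthology copy-number profiling of candidate gene families.

Orthology databases cluster proteins independently at nested taxonomic levels
(e.g. Metazoa > Arthropoda > Hexapoda > Insecta).  For a gene family of
interest this module ingests those per-level clustering tables, curates group
members (collapsing redundant isoforms, dropping partial or oversized
proteins), resolves one copy number per species by giving precedence to the
most taxonomically restrictive level covering that species, flags species
whose presence depends on a wider-level clustering only (discordances), calls
clade-wide losses and duplications against the taxonomy, and renders a
species-per-box presence/copy-number grid.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Taxonomy",
    "TaxonomyNode",
    "OrthologyGroup",
    "CopyNumberProfile",
    "LossCall",
    "DuplicationCall",
    "load_orthogroup_tables",
    "curate_members",
    "copy_number",
    "reconcile_levels",
    "profile_from_tables",
    "call_clade_events",
    "render_profile",
    "profile_to_frame",
    "read_profile_tsv",
    "export_fasta",
    "ingest_newick",
]

# protein_id prefix before the last '-' or '.' token identifies the gene locus
DEFAULT_LOCUS_REGEX = r"^(?P<locus>.+)[-.][^-.]+$"
LENGTH_MIN_FRAC = 0.40
LENGTH_MAX_FRAC = 2.50


# ---------------------------------------------------------------------------
# Taxonomy

@dataclass
class TaxonomyNode:
    name: str
    parent: "TaxonomyNode | None" = None
    children: list["TaxonomyNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def species(self) -> list[str]:
        """Leaf species names under this node (a leaf returns itself)."""
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        stack = list(self.children)
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            else:
                stack.extend(n.children)
        return sorted(out)


class Taxonomy:
    """A rooted hierarchy of named clades with species at the leaves."""

    def __init__(self, root: TaxonomyNode):
        self.root = root
        self.nodes: dict[str, TaxonomyNode] = {}
        stack = [root]
        while stack:
            n = stack.pop()
            if n.name in self.nodes:
                raise ValueError(f"duplicate taxonomy node name: {n.name}")
            self.nodes[n.name] = n
            stack.extend(n.children)
        self.species: frozenset[str] = frozenset(
            n.name for n in self.nodes.values() if n.is_leaf
        )

    @classmethod
    def from_indented(cls, text: str) -> "Taxonomy":
        """Parse an indented outline (two spaces per level; leaves = species)."""
        root: TaxonomyNode | None = None
        stack: list[tuple[int, TaxonomyNode]] = []
        for raw in text.splitlines():
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            depth = (len(raw) - len(raw.lstrip())) // 2
            node = TaxonomyNode(raw.strip())
            if depth == 0:
                if root is not None:
                    raise ValueError("taxonomy must have a single root")
                root = node
                stack = [(0, node)]
                continue
            while stack and stack[-1][0] >= depth:
                stack.pop()
            if not stack:
                raise ValueError(f"bad indentation at {node.name!r}")
            parent = stack[-1][1]
            node.parent = parent
            parent.children.append(node)
            stack.append((depth, node))
        if root is None:
            raise ValueError("empty taxonomy")
        return cls(root)

    @classmethod
    def from_newick(cls, path: str | Path) -> "Taxonomy":
        """Build from a newick file with named internal nodes (clade labels)."""
        from Bio import Phylo

        tree = Phylo.read(str(path), "newick")

        def convert(clade, parent=None):
            name = clade.name or clade.confidence
            node = TaxonomyNode(str(name), parent=parent)
            for c in clade.clades:
                node.children.append(convert(c, node))
            return node

        return cls(convert(tree.root))

    @classmethod
    def load(cls, path: str | Path) -> "Taxonomy":
        path = Path(path)
        text = path.read_text()
        if text.lstrip().startswith("("):
            return cls.from_newick(path)
        return cls.from_indented(text)

    def clade_species(self, name: str) -> list[str]:
        return self.nodes[name].species()

    def path_to_root(self, species: str) -> list[str]:
        """Clade names from the species leaf up to the root."""
        node = self.nodes[species]
        out = []
        while node is not None:
            out.append(node.name)
            node = node.parent
        return out

    def most_restrictive(self, species: str, levels: Iterable[str]) -> str:
        """The smallest of ``levels`` whose clade contains ``species``."""
        containing = [
            lvl for lvl in levels if species in set(self.clade_species(lvl))
        ]
        if not containing:
            raise KeyError(f"species {species!r} covered by no clustering level")
        return min(containing, key=lambda lvl: len(self.clade_species(lvl)))

    def nearest_sister_species(self, clade: str, sampled: set[str]) -> list[str]:
        """Sampled species of the nearest sibling clade with any sampling.

        Walks up the tree from ``clade`` and returns the sampled species found
        outside the clade at the first ancestor where some exist.
        """
        node = self.nodes[clade]
        inside = set(node.species())
        anc = node.parent
        while anc is not None:
            out = [s for s in anc.species() if s in sampled and s not in inside]
            if out:
                return out
            anc = anc.parent
        return []


# ---------------------------------------------------------------------------
# Orthology groups

@dataclass
class OrthologyGroup:
    """One orthology cluster at one taxonomic level.

    ``members`` maps species -> list of (protein_id, length_aa).
    """

    level: str
    og_id: str
    members: dict[str, list[tuple[str, int]]]

    def total_members(self) -> int:
        return sum(len(v) for v in self.members.values())


def load_orthogroup_tables(
    tables: pd.DataFrame | Sequence[str | Path],
    taxonomy: Taxonomy,
) -> dict[str, dict[str, OrthologyGroup]]:
    """Validate and index orthogroup tables as {level: {og_id: group}}.

    Accepts a single DataFrame or paths to TSVs with columns
    (level, og_id, species, protein_id, length).  Species absent from the
    taxonomy raise an error naming the offenders; duplicate
    (level, og_id, species, protein_id) rows are dropped with a warning.
    """
    if isinstance(tables, pd.DataFrame):
        df = tables.copy()
    else:
        frames = []
        for p in tables:
            try:
                frames.append(pd.read_csv(p, sep="\t", dtype={"og_id": str}))
            except Exception as exc:  # pragma: no cover - pandas reports line numbers
                raise ValueError(f"malformed orthogroup table {p}: {exc}") from exc
        df = pd.concat(frames, ignore_index=True)

    required = {"level", "og_id", "species", "protein_id", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"orthogroup table missing columns: {sorted(missing)}")
    bad_len = df[~df["length"].apply(lambda x: np.isreal(x) and x > 0)]
    if not bad_len.empty:
        raise ValueError(
            f"non-positive or non-numeric length at rows {list(bad_len.index[:5])}"
        )
    unknown = sorted(set(df["species"]) - taxonomy.species)
    if unknown:
        raise ValueError(f"species absent from taxonomy: {unknown}")

    dup_mask = df.duplicated(["level", "og_id", "species", "protein_id"])
    if dup_mask.any():
        warnings.warn(f"dropping {int(dup_mask.sum())} duplicate member rows")
        df = df[~dup_mask]

    out: dict[str, dict[str, OrthologyGroup]] = {}
    for (level, og_id), grp in df.groupby(["level", "og_id"]):
        clade = set(taxonomy.clade_species(level))
        outside = sorted(set(grp["species"]) - clade)
        if outside:
            raise ValueError(
                f"group {og_id} at level {level} has species outside the clade: {outside}"
            )
        members: dict[str, list[tuple[str, int]]] = {}
        for _, row in grp.iterrows():
            members.setdefault(row["species"], []).append(
                (row["protein_id"], int(row["length"]))
            )
        out.setdefault(level, {})[str(og_id)] = OrthologyGroup(level, str(og_id), members)
    return out


def curate_members(
    group: OrthologyGroup,
    *,
    locus_regex: str = DEFAULT_LOCUS_REGEX,
    min_frac: float = LENGTH_MIN_FRAC,
    max_frac: float = LENGTH_MAX_FRAC,
) -> tuple[OrthologyGroup, list[dict]]:
    """Collapse redundant isoforms and drop partial/oversized members.

    (i) members of one species sharing a gene-locus key (``locus_regex``
    applied to the protein id; ids that do not match are their own locus)
    collapse to the longest isoform; (ii) members shorter than ``min_frac``
    or longer than ``max_frac`` of the within-group median length (computed
    after isoform collapse) are removed as partial / overly large.  Returns
    the curated group and a removal log.
    """
    pat = re.compile(locus_regex)
    log: list[dict] = []
    deduped: dict[str, list[tuple[str, int]]] = {}
    for sp, members in group.members.items():
        by_locus: dict[str, list[tuple[str, int]]] = {}
        for pid, length in members:
            m = pat.match(pid)
            key = m.group("locus") if m else pid
            by_locus.setdefault(key, []).append((pid, length))
        kept = []
        for key, isoforms in by_locus.items():
            isoforms.sort(key=lambda t: (-t[1], t[0]))
            kept.append(isoforms[0])
            for pid, length in isoforms[1:]:
                log.append({"species": sp, "protein_id": pid,
                            "reason": f"redundant_isoform_of:{isoforms[0][0]}"})
        deduped[sp] = kept

    lengths = [l for mem in deduped.values() for _, l in mem]
    curated: dict[str, list[tuple[str, int]]] = {}
    if lengths:
        med = float(np.median(lengths))
        for sp, members in deduped.items():
            kept = []
            for pid, length in members:
                if length < min_frac * med:
                    log.append({"species": sp, "protein_id": pid,
                                "reason": f"partial:{length}aa<{min_frac:.0%}_of_median_{med:.0f}"})
                elif length > max_frac * med:
                    log.append({"species": sp, "protein_id": pid,
                                "reason": f"oversized:{length}aa>{max_frac:.0%}_of_median_{med:.0f}"})
                else:
                    kept.append((pid, length))
            if kept:
                curated[sp] = kept
    return OrthologyGroup(group.level, group.og_id, curated), log


def copy_number(group: OrthologyGroup, clade_species: Iterable[str]) -> dict[str, int]:
    """Retained members per species; clade species absent from the group get 0."""
    counts = {sp: 0 for sp in clade_species}
    for sp, members in group.members.items():
        counts[sp] = len(members)
    return counts


# ---------------------------------------------------------------------------
# Cross-level reconciliation and event calls

@dataclass
class CopyNumberProfile:
    gene_family: str
    counts: dict[str, int]            # species -> resolved copy number
    source_level: dict[str, str]      # species -> level the count came from
    discordant: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("copy numbers must be non-negative")
        if set(self.counts) != set(self.source_level):
            raise ValueError("every species needs a recorded source level")


@dataclass(frozen=True)
class LossCall:
    clade: str
    n_absent: int
    outgroup_present: int
    call: str  # clade_loss | partial | retained


@dataclass(frozen=True)
class DuplicationCall:
    clade: str
    n_multi: int
    n_species: int


def reconcile_levels(
    level_counts: Mapping[str, Mapping[str, int]],
    taxonomy: Taxonomy,
    gene_family: str = "family",
) -> CopyNumberProfile:
    """Resolve one copy number per species across clustering levels.

    Each species takes its count from the most taxonomically restrictive
    (last-common-ancestor) level whose clade contains it — the most specific
    and reliable clustering.  A species with 0 there but > 0 at a wider level
    keeps the 0 and is flagged discordant: its presence rests on the
    wider-level clustering only.
    """
    all_species = sorted({sp for counts in level_counts.values() for sp in counts})
    counts: dict[str, int] = {}
    source: dict[str, str] = {}
    discordant: set[str] = set()
    for sp in all_species:
        covering = [lvl for lvl in level_counts if sp in level_counts[lvl]]
        if not covering:
            raise KeyError(f"species {sp!r} present in no level profile")
        lvl = taxonomy.most_restrictive(sp, covering)
        c = int(level_counts[lvl][sp])
        counts[sp] = c
        source[sp] = lvl
        if c == 0 and any(level_counts[w][sp] > 0 for w in covering if w != lvl):
            discordant.add(sp)
    return CopyNumberProfile(gene_family, counts, source, discordant)


def profile_from_tables(
    tables: pd.DataFrame | Sequence[str | Path],
    taxonomy: Taxonomy,
    gene_family: str = "family",
    **curation_kwargs,
) -> tuple[CopyNumberProfile, list[dict]]:
    """Full small-scale pipeline: load -> curate -> count -> reconcile.

    Copy numbers of multiple orthogroups at the same level are summed per
    species before reconciliation.  Returns the resolved profile and the
    concatenated curation removal log.
    """
    levels = load_orthogroup_tables(tables, taxonomy)
    level_counts: dict[str, dict[str, int]] = {}
    removal_log: list[dict] = []
    for level, groups in levels.items():
        merged = {sp: 0 for sp in taxonomy.clade_species(level)}
        for group in groups.values():
            curated, log = curate_members(group, **curation_kwargs)
            removal_log.extend(log)
            for sp, n in copy_number(curated, taxonomy.clade_species(level)).items():
                merged[sp] += n
        level_counts[level] = merged
    return reconcile_levels(level_counts, taxonomy, gene_family), removal_log


def call_clade_events(
    profile: CopyNumberProfile,
    taxonomy: Taxonomy,
    *,
    min_species: int = 3,
    dup_fraction: float = 0.80,
) -> tuple[list[LossCall], list[DuplicationCall]]:
    """Call clade-wide losses and duplications on the resolved profile.

    A clade loss requires every sampled species of a clade (at least
    ``min_species`` of them, to avoid calling scattered single-species
    absences that may reflect limited transcriptomic evidence) to have 0
    copies while the nearest sister clade retains the family.  A clade
    duplication requires at least ``dup_fraction`` of sampled species to hold
    2+ copies.  Traversal is top-down; once an event is called for a clade
    its subclades are not reported separately, so calls are maximal.
    """
    sampled = set(profile.counts)
    losses: list[LossCall] = []
    dups: list[DuplicationCall] = []

    def visit(node: TaxonomyNode) -> None:
        if node.is_leaf:
            return
        species = [s for s in node.species() if s in sampled]
        if len(species) >= min_species:
            counts = [profile.counts[s] for s in species]
            if all(c == 0 for c in counts):
                sisters = taxonomy.nearest_sister_species(node.name, sampled)
                present = sum(profile.counts[s] >= 1 for s in sisters)
                if present >= 1:
                    losses.append(LossCall(node.name, len(species), present, "clade_loss"))
                    return  # subclades of a lost clade are implied
            n_multi = sum(c >= 2 for c in counts)
            if n_multi >= dup_fraction * len(species) and n_multi > 0:
                dups.append(DuplicationCall(node.name, n_multi, len(species)))
                return
        for child in node.children:
            visit(child)

    visit(taxonomy.root)
    return losses, dups


# ---------------------------------------------------------------------------
# Rendering and round-trip

COPY_COLORS = {0: "#d9d9d9", 1: "#74add1", 2: "#f46d43", 3: "#a50026"}


def profile_to_frame(profile: CopyNumberProfile, taxonomy: Taxonomy,
                     clade_rank: str | None = None) -> pd.DataFrame:
    """Tidy species x family table: species, clade, copy_number, source_level,
    discordant.  ``clade_rank`` picks the row grouping (default: children of
    the taxonomy root)."""
    if clade_rank is None:
        row_clades = [c.name for c in taxonomy.root.children if not c.is_leaf]
    else:
        row_clades = [clade_rank]
    rows = []
    for clade in row_clades:
        for sp in taxonomy.clade_species(clade):
            if sp not in profile.counts:
                continue
            rows.append({
                "species": sp,
                "clade": clade,
                "gene_family": profile.gene_family,
                "copy_number": profile.counts[sp],
                "source_level": profile.source_level[sp],
                "discordant": sp in profile.discordant,
            })
    return pd.DataFrame(rows)


def read_profile_tsv(path: str | Path) -> CopyNumberProfile:
    """Re-read a matrix TSV written by :func:`render_profile` (lossless)."""
    df = pd.read_csv(path, sep="\t")
    return CopyNumberProfile(
        gene_family=str(df["gene_family"].iloc[0]),
        counts={r.species: int(r.copy_number) for r in df.itertuples()},
        source_level={r.species: str(r.source_level) for r in df.itertuples()},
        discordant={r.species for r in df.itertuples() if bool(r.discordant)},
    )


def render_profile(
    profile: CopyNumberProfile,
    taxonomy: Taxonomy,
    out_prefix: str | Path,
    *,
    palette: Mapping[int, str] = COPY_COLORS,
    formats: Sequence[str] = ("svg",),
) -> pd.DataFrame:
    """Render the taxonomy-ordered copy-number grid and write the matrix TSV.

    One row per clade; one box per sampled species, sorted ascending by copy
    number (ties broken by species name), colored by count category
    {0, 1, 2, >=3}; discordant species carry a white asterisk.  Writes
    ``<prefix>.tsv`` plus one image per requested format and returns the tidy
    table.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    df = profile_to_frame(profile, taxonomy)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_prefix.with_suffix(".tsv"), sep="\t", index=False)

    clades = list(dict.fromkeys(df["clade"])) if not df.empty else []
    n_rows = max(len(clades), 1)
    width = max(df.groupby("clade").size().max() if not df.empty else 1, 1)
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * width + 2), 0.5 * n_rows + 1.2))
    for yi, clade in enumerate(clades):
        sub = df[df["clade"] == clade].sort_values(["copy_number", "species"])
        for xi, row in enumerate(sub.itertuples()):
            color = palette[min(row.copy_number, 3)]
            ax.add_patch(plt.Rectangle((xi, n_rows - 1 - yi), 0.9, 0.9,
                                       facecolor=color, edgecolor="black", lw=0.3))
            if row.discordant:
                ax.text(xi + 0.45, n_rows - 1 - yi + 0.45, "*", color="white",
                        ha="center", va="center", fontsize=11, fontweight="bold")
    ax.set_yticks([n_rows - 1 - i + 0.45 for i in range(len(clades))])
    ax.set_yticklabels(clades)
    ax.set_xlim(0, width)
    ax.set_ylim(0, n_rows)
    ax.set_xticks([])
    ax.set_title(f"{profile.gene_family} distribution")
    ax.legend(
        handles=[Patch(facecolor=palette[k], edgecolor="black",
                       label=str(k) if k < 3 else ">=3") for k in sorted(palette)],
        loc="upper right", fontsize=7, title="copies",
    )
    for fmt in formats:
        fig.savefig(out_prefix.with_suffix(f".{fmt}"), bbox_inches="tight")
    plt.close(fig)
    return df


# ---------------------------------------------------------------------------
# Sequence export / tree ingestion

def export_fasta(
    group: OrthologyGroup,
    sequences: Mapping[str, str],
    path: str | Path,
) -> list[str]:
    """Write group members as FASTA with ``species|protein_id`` headers.

    Returns the list of protein ids with no sequence available (skipped).
    """
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records, missing = [], []
    for sp in sorted(group.members):
        for pid, _length in sorted(group.members[sp]):
            seq = sequences.get(pid)
            if seq is None:
                missing.append(pid)
                continue
            records.append(SeqRecord(Seq(seq), id=f"{sp}|{pid}", description=""))
    seqio_write(records, str(path), "fasta")
    return missing


def ingest_newick(path: str | Path, taxonomy: Taxonomy,
                  clade_rank: str | None = None):
    """Read a newick tree and annotate leaves with their taxonomy clade.

    Leaf names of the form ``species|protein_id`` (or bare species names) are
    matched to taxonomy species; unmatched leaves trigger a warning and stay
    unannotated.  Returns ``(tree, {leaf_name: clade})``.
    """
    from Bio import Phylo

    tree = Phylo.read(str(path), "newick")
    if clade_rank is None:
        row_clades = [c.name for c in taxonomy.root.children if not c.is_leaf]
    else:
        row_clades = [clade_rank]
    sp_to_clade = {
        sp: clade for clade in row_clades for sp in taxonomy.clade_species(clade)
    }
    annotations: dict[str, str] = {}
    for leaf in tree.get_terminals():
        species = (leaf.name or "").split("|")[0]
        if species in sp_to_clade:
            annotations[leaf.name] = sp_to_clade[species]
        else:
            warnings.warn(f"newick leaf {leaf.name!r} not in taxonomy; unannotated")
    return tree, annotations
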