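"""Clade database construction: tree scaling, candidate clades, SNV barcodes.

Takes a rooted species phylogeny (bootstrap support on internal nodes) plus
a filtered :class:`~cladecall.counts.GenotypeMatrix` and produces a
hierarchical database of accepted clades, each tagged with its
clade-specific allele barcode.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .counts import EmptyDatabaseError, GenotypeMatrix, N_CODE, _CODE_TO_CHAR, _CHAR_TO_CODE

__all__ = [
    "hamming_distance",
    "pairwise_hamming",
    "read_tree",
    "scale_tree",
    "dereplicate_genomes",
    "enumerate_candidate_clades",
    "find_clade_specific_alleles",
    "build_database",
    "ScaledPhylogeny",
    "CandidateClade",
    "CladeBarcode",
    "ReferenceDatabase",
    "UnscaledTreeError",
]


class UnscaledTreeError(RuntimeError):
    """Branch lengths are not in SNV units and a rule requiring them was used."""


def hamming_distance(calls_a: np.ndarray, calls_b: np.ndarray) -> int:
    """SNV distance: positions where both calls are non-N and differ.

    Symmetric by construction. N-masking means the triangle inequality is
    not guaranteed.
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    both = (a != N_CODE) & (b != N_CODE)
    return int(np.count_nonzero(both & (a != b)))


def pairwise_hamming(genotypes: GenotypeMatrix) -> np.ndarray:
    """Dense symmetric matrix of pairwise SNV distances."""
    n = genotypes.n_genomes
    d = np.zeros((n, n), dtype=np.int64)
    calls = genotypes.calls
    for i in range(n):
        ai = calls[i]
        mask_i = ai != N_CODE
        for j in range(i + 1, n):
            bj = calls[j]
            both = mask_i & (bj != N_CODE)
            d[i, j] = d[j, i] = np.count_nonzero(both & (ai != bj))
    return d


# ---------------------------------------------------------------------------
# Trees

def _parse_support(label: str | None) -> float | None:
    if label is None or label == "":
        return None
    try:
        v = float(label)
    except ValueError:
        return None
    return v / 100.0 if v > 1.0 else v


def read_tree(path, schema: str = "newick") -> dendropy.Tree:
    """Read a Newick/NEXUS tree; midpoint-root it if unrooted.

    Bootstrap support is taken from internal node labels; values above 1
    are interpreted as percentages and divided by 100.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema=schema, preserve_underscores=True
    )
    if not tree.is_rooted:
        tree.is_rooted = True
        tree.reroot_at_midpoint(update_bipartitions=True, suppress_unifurcations=True)
    for node in tree.preorder_node_iter():
        node.support = _parse_support(node.label) if not node.is_leaf() else None
    return tree


@dataclass
class ScaledPhylogeny:
    """Rooted tree whose branch lengths are (when possible) in SNV units."""

    tree: dendropy.Tree
    scale_unit: str            # "SNVs" or "raw"
    slope: float               # multiplier applied to raw branch lengths
    pearson_r: float

    @property
    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


def scale_tree(
    tree: dendropy.Tree, genotypes: GenotypeMatrix, min_r: float = 0.75
) -> ScaledPhylogeny:
    """Rescale branch lengths into SNV units via the genotype distances.

    Pairwise patristic distances are regressed (through the origin) onto
    pairwise SNV distances.  If their Pearson correlation exceeds
    ``min_r``, every branch length is multiplied by the fitted slope and
    the result is flagged ``scale_unit="SNVs"``; otherwise lengths are
    left untouched (``"raw"``).
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValueError("need at least 3 leaves to correlate distances")
    labels = [lf.taxon.label for lf in leaves]
    missing = set(labels) - set(genotypes.genome_ids)
    if missing:
        raise ValueError(f"tree leaves missing from genotypes: {sorted(missing)}")

    pdm = tree.phylogenetic_distance_matrix()
    idx = {g: i for i, g in enumerate(genotypes.genome_ids)}
    ham = pairwise_hamming(genotypes)
    pat, snv = [], []
    for i in range(len(leaves)):
        for j in range(i + 1, len(leaves)):
            pat.append(pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon))
            snv.append(ham[idx[labels[i]], idx[labels[j]]])
    pat = np.asarray(pat, dtype=float)
    snv = np.asarray(snv, dtype=float)

    if pat.std() == 0 or snv.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pat, snv)[0, 1])
    denom = float(np.sum(pat * pat))
    slope = float(np.sum(pat * snv) / denom) if denom > 0 else 0.0

    if r > min_r and slope > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * slope
        return ScaledPhylogeny(tree, "SNVs", slope, r)
    return ScaledPhylogeny(tree, "raw", 1.0, r)


def dereplicate_genomes(
    genotypes: GenotypeMatrix,
    epsilon: float = 500.0,
    min_cluster: int = 2,
    median_coverage: dict[str, float] | None = None,
) -> list[str]:
    """Density-cluster genomes at ``epsilon`` SNVs; keep one per cluster.

    The representative of each cluster is the member with the highest
    median coverage (ties broken lexicographically by genome id); all
    noise points (singletons) are retained.
    """
    from sklearn.cluster import DBSCAN

    n = genotypes.n_genomes
    if n == 0:
        return []
    if n == 1:
        return list(genotypes.genome_ids)
    d = pairwise_hamming(genotypes).astype(float)
    labels = DBSCAN(eps=epsilon, min_samples=min_cluster, metric="precomputed").fit(d).labels_

    cov = median_coverage or {}
    reps: list[str] = []
    for lab in sorted(set(labels)):
        ids = [genotypes.genome_ids[i] for i in np.flatnonzero(labels == lab)]
        if lab == -1:
            reps.extend(sorted(ids))
        else:
            reps.append(min(ids, key=lambda g: (-cov.get(g, 0.0), g)))
    return sorted(reps)


# ---------------------------------------------------------------------------
# Candidate clades and barcodes

@dataclass
class CandidateClade:
    clade_id: str
    members: list[str]              # sorted genome ids
    branch_length: float            # subtending-branch length, SNV units
    bootstrap: float
    accepted: bool = True

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class CladeBarcode:
    clade_id: str
    snvs: list[tuple[int, int]]     # (1-based position, allele code 0..3)

    @property
    def size(self) -> int:
        return len(self.snvs)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for p, _ in self.snvs], dtype=np.int64)

    @property
    def alleles(self) -> np.ndarray:
        return np.array([a for _, a in self.snvs], dtype=np.uint8)


def enumerate_candidate_clades(
    phylo: ScaledPhylogeny,
    min_genomes: int = 4,
    min_branch: float = 1000.0,
    min_bootstrap: float = 0.75,
    allow_raw_lengths: bool = False,
    missing_bootstrap: float = 0.0,
) -> list[CandidateClade]:
    """Internal nodes whose clade passes size, branch-length and support rules.

    Acceptance requires >= ``min_genomes`` members, a subtending branch of
    at least ``min_branch`` SNVs, and bootstrap strictly above
    ``min_bootstrap``.  The two branches adjacent to the root are excluded
    (midpoint-rooting artefact guard).  Nested acceptance is allowed and is
    what produces the hierarchical levels.
    """
    if phylo.scale_unit != "SNVs" and not allow_raw_lengths:
        raise UnscaledTreeError(
            "tree branch lengths are not in SNV units; pass allow_raw_lengths=True "
            "to apply the branch-length criterion to raw lengths"
        )
    root = phylo.tree.seed_node
    out: list[CandidateClade] = []
    counter = 0
    for node in phylo.tree.preorder_node_iter():
        if node.is_leaf() or node is root or node.parent_node is root:
            continue
        counter += 1
        members = sorted(lf.taxon.label for lf in node.leaf_iter())
        length = node.edge.length or 0.0
        support = node.support if node.support is not None else missing_bootstrap
        if len(members) >= min_genomes and length >= min_branch and support > min_bootstrap:
            out.append(
                CandidateClade(f"clade_{counter:03d}", members, float(length), float(support))
            )
    return out


def find_clade_specific_alleles(
    clade: CandidateClade,
    genotypes: GenotypeMatrix,
    outgroups: GenotypeMatrix | None = None,
    max_inclade_ambig: float = 0.10,
    max_outgroup_nonambig: float = 0.10,
) -> CladeBarcode:
    """Alleles carried unanimously by a clade and absent everywhere else.

    A (position, allele) pair enters the barcode when every non-N in-clade
    call is that allele, fewer than ``max_inclade_ambig`` of in-clade calls
    are N, and no genome outside the clade (any non-member, not just other
    accepted clades) carries the allele.  When ``outgroups`` is supplied,
    positions that are non-N in more than ``max_outgroup_nonambig`` of
    outgroup genomes are discarded entirely.
    """
    idx = {g: i for i, g in enumerate(genotypes.genome_ids)}
    in_idx = np.array([idx[g] for g in clade.members])
    out_idx = np.array([i for i in range(genotypes.n_genomes) if genotypes.genome_ids[i] not in set(clade.members)])

    calls = genotypes.calls.astype(np.int16)
    sub = calls[in_idx]                                  # (k, P)
    non_n = sub != N_CODE
    frac_n = 1.0 - non_n.mean(axis=0)

    lo = np.where(non_n, sub, 99).min(axis=0)
    hi = np.where(non_n, sub, -1).max(axis=0)
    unanimous = (lo == hi) & (hi >= 0)
    ok = unanimous & (frac_n < max_inclade_ambig)

    allele = np.where(ok, hi, -1)
    if len(out_idx):
        carried_outside = (calls[out_idx] == allele[None, :]).any(axis=0)
        ok &= ~carried_outside

    if outgroups is not None:
        if not np.array_equal(outgroups.positions, genotypes.positions):
            raise ValueError("outgroup genotypes must share the in-group position set")
        og_non_n = (outgroups.calls != N_CODE).mean(axis=0)
        ok &= og_non_n <= max_outgroup_nonambig

    # barcode alleles must actually differ from the background consensus,
    # which is implied by "not carried outside" whenever any non-member is
    # non-N; drop candidates where every non-member is N at the position
    snvs = [
        (int(genotypes.positions[j]), int(allele[j]))
        for j in np.flatnonzero(ok)
    ]
    return CladeBarcode(clade.clade_id, snvs)


# ---------------------------------------------------------------------------
# Reference database

@dataclass
class ReferenceDatabase:
    phylogeny: ScaledPhylogeny | None
    clades: list[CandidateClade]
    barcodes: dict[str, CladeBarcode]
    levels: dict[str, int]
    parameters: dict[str, str] = field(default_factory=dict)

    @property
    def clade_ids(self) -> list[str]:
        return [c.clade_id for c in self.clades]

    @property
    def informative_positions(self) -> np.ndarray:
        pos = sorted({p for bc in self.barcodes.values() for p, _ in bc.snvs})
        return np.array(pos, dtype=np.int64)

    def clade(self, clade_id: str) -> CandidateClade:
        for c in self.clades:
            if c.clade_id == clade_id:
                return c
        raise KeyError(clade_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceDatabase):
            return NotImplemented
        return (
            [(c.clade_id, c.members, c.branch_length, c.bootstrap) for c in self.clades]
            == [(c.clade_id, c.members, c.branch_length, c.bootstrap) for c in other.clades]
            and {k: v.snvs for k, v in self.barcodes.items()}
            == {k: v.snvs for k, v in other.barcodes.items()}
            and self.levels == other.levels
            and self.parameters == other.parameters
        )

    # -- serialization: a directory of four plain-text files ----------------

    def save(self, path) -> None:
        os.makedirs(path, exist_ok=True)
        with open(os.path.join(path, "params.tsv"), "w") as fh:
            for k in sorted(self.parameters):
                fh.write(f"{k}\t{self.parameters[k]}\n")
        with open(os.path.join(path, "clades.tsv"), "w") as fh:
            fh.write("clade_id\tlevel\tn_members\tbranch_length\tbootstrap\tmembers\n")
            for c in self.clades:
                fh.write(
                    f"{c.clade_id}\t{self.levels[c.clade_id]}\t{c.n_members}\t"
                    f"{c.branch_length!r}\t{c.bootstrap!r}\t{','.join(c.members)}\n"
                )
        with open(os.path.join(path, "barcodes.tsv"), "w") as fh:
            fh.write("clade_id\tposition\tallele\n")
            for c in self.clades:
                for pos, a in self.barcodes[c.clade_id].snvs:
                    fh.write(f"{c.clade_id}\t{pos}\t{_CODE_TO_CHAR[a]}\n")
        if self.phylogeny is not None:
            self.phylogeny.tree.write(
                path=os.path.join(path, "tree.nwk"),
                schema="newick",
                unquoted_underscores=True,
            )

    @classmethod
    def load(cls, path) -> "ReferenceDatabase":
        params: dict[str, str] = {}
        ppath = os.path.join(path, "params.tsv")
        if os.path.exists(ppath):
            with open(ppath) as fh:
                for line in fh:
                    if line.strip():
                        k, _, v = line.rstrip("\n").partition("\t")
                        params[k] = v
        clades: list[CandidateClade] = []
        levels: dict[str, int] = {}
        with open(os.path.join(path, "clades.tsv")) as fh:
            fh.readline()
            for line in fh:
                cid, lvl, _, bl, bs, members = line.rstrip("\n").split("\t")
                clades.append(
                    CandidateClade(cid, members.split(","), float(bl), float(bs))
                )
                levels[cid] = int(lvl)
        barcodes: dict[str, CladeBarcode] = {c.clade_id: CladeBarcode(c.clade_id, []) for c in clades}
        with open(os.path.join(path, "barcodes.tsv")) as fh:
            fh.readline()
            for line in fh:
                cid, pos, allele = line.rstrip("\n").split("\t")
                barcodes[cid].snvs.append((int(pos), _CHAR_TO_CODE[allele]))
        phylo = None
        tpath = os.path.join(path, "tree.nwk")
        if os.path.exists(tpath):
            tree = read_tree(tpath)
            phylo = ScaledPhylogeny(
                tree,
                params.get("scale_unit", "SNVs"),
                float(params.get("scale_slope", 1.0)),
                float(params.get("scale_pearson_r", 1.0)),
            )
        return cls(phylo, clades, barcodes, levels, params)


def assign_levels(clades: list[CandidateClade]) -> dict[str, int]:
    """Nesting depth of each clade within the accepted set.

    Level 0 clades have no accepted ancestor; a clade's level is the number
    of accepted clades whose member set strictly contains its own.  Clades
    at the same level are guaranteed disjoint by tree structure.
    """
    sets = {c.clade_id: frozenset(c.members) for c in clades}
    levels = {}
    for c in clades:
        s = sets[c.clade_id]
        levels[c.clade_id] = sum(
            1 for other in clades
            if other.clade_id != c.clade_id and s < sets[other.clade_id]
        )
    return levels


def build_database(
    phylo: ScaledPhylogeny,
    genotypes: GenotypeMatrix,
    outgroups: GenotypeMatrix | None = None,
    min_genomes: int = 4,
    min_branch: float = 1000.0,
    min_bootstrap: float = 0.75,
    min_cssnvs: int = 10,
    max_inclade_ambig: float = 0.10,
    max_outgroup_nonambig: float = 0.10,
    allow_raw_lengths: bool = False,
) -> ReferenceDatabase:
    """Assemble the clade database: candidates -> barcodes -> pruning.

    Candidate clades whose barcode holds fewer than ``min_cssnvs``
    clade-specific SNVs are removed.  Raises
    :class:`~cladecall.counts.EmptyDatabaseError` when nothing survives.
    """
    candidates = enumerate_candidate_clades(
        phylo, min_genomes, min_branch, min_bootstrap, allow_raw_lengths
    )
    kept: list[CandidateClade] = []
    barcodes: dict[str, CladeBarcode] = {}
    for clade in candidates:
        bc = find_clade_specific_alleles(
            clade, genotypes, outgroups, max_inclade_ambig, max_outgroup_nonambig
        )
        if bc.size >= min_cssnvs:
            kept.append(clade)
            barcodes[clade.clade_id] = bc
    if not kept:
        raise EmptyDatabaseError(
            "no candidate clade passed the barcode-size criterion "
            f"({len(candidates)} candidates examined)"
        )
    levels = assign_levels(kept)
    params = {
        "min_genomes": str(min_genomes),
        "min_branch": repr(float(min_branch)),
        "min_bootstrap": repr(float(min_bootstrap)),
        "min_cssnvs": str(min_cssnvs),
        "max_inclade_ambig": repr(float(max_inclade_ambig)),
        "max_outgroup_nonambig": repr(float(max_outgroup_nonambig)),
        "scale_unit": phylo.scale_unit,
        "scale_slope": repr(float(phylo.slope)),
        "scale_pearson_r": repr(float(phylo.pearson_r)),
    }
    return ReferenceDatabase(phylo, kept, barcodes, levels, params)
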