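import numpy as np
import pytest

from cladecall.counts import EmptyDatabaseError, GenotypeMatrix, N_CODE, encode_calls
from cladecall.phylo import (
    CandidateClade,
    ReferenceDatabase,
    ScaledPhylogeny,
    UnscaledTreeError,
    build_database,
    dereplicate_genomes,
    enumerate_candidate_clades,
    find_clade_specific_alleles,
    hamming_distance,
    pairwise_hamming,
    read_tree,
    scale_tree,
)


def geno(rows: dict[str, str], positions=None) -> GenotypeMatrix:
    ids = list(rows)
    calls = np.stack([encode_calls(rows[g]) for g in ids])
    P = calls.shape[1]
    return GenotypeMatrix(ids, positions or np.arange(1, P + 1), calls)


def tree_from(newick: str, tmp_path):
    path = tmp_path / "t.nwk"
    path.write_text(newick + "\n")
    return read_tree(path)


# ---------------------------------------------------------------------------
# Hamming distance

def test_hamming_identical():
    a = encode_calls("ACGT")
    assert hamming_distance(a, a) == 0


def test_hamming_single_diff():
    assert hamming_distance(encode_calls("ACG"), encode_calls("ATG")) == 1


def test_hamming_skips_n():
    assert hamming_distance(encode_calls("ANG"), encode_calls("ATT")) == 1


def test_hamming_length_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        hamming_distance(encode_calls("AC"), encode_calls("ACG"))


def test_hamming_symmetric_random():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.integers(0, 5, 30).astype(np.uint8)
        b = rng.integers(0, 5, 30).astype(np.uint8)
        brute = sum(
            1 for x, y in zip(a, b) if x != 4 and y != 4 and x != y
        )
        assert hamming_distance(a, b) == hamming_distance(b, a) == brute


# ---------------------------------------------------------------------------
# Tree scaling

def test_scale_tree_exact_snv_lengths(tmp_path):
    # a: 1 private SNV, b: 1, c: 3  ->  patristic == SNV distance exactly
    g = geno({
        "a": "CAAAA",
        "b": "ACAAA",
        "c": "AACCC",
    })
    tree = tree_from("[&R] (a:1,b:1,c:3);", tmp_path)
    phylo = scale_tree(tree, g)
    assert phylo.scale_unit == "SNVs"
    assert phylo.pearson_r == pytest.approx(1.0)
    assert phylo.slope == pytest.approx(1.0)


def test_scale_tree_star_uncorrelated(tmp_path):
    g = geno({"a": "CAAA", "b": "ACAA", "c": "AACA", "d": "AAAC"})
    tree = tree_from("[&R] (a:5,b:5,c:5,d:5);", tmp_path)
    phylo = scale_tree(tree, g)
    assert phylo.scale_unit == "raw"
    assert phylo.slope == 1.0


def test_scale_tree_too_few_leaves(tmp_path):
    g = geno({"a": "CA", "b": "AC"})
    tree = tree_from("[&R] (a:1,b:1);", tmp_path)
    with pytest.raises(ValueError, match="3 leaves"):
        scale_tree(tree, g)


def test_scale_tree_missing_leaf(tmp_path):
    g = geno({"a": "CA", "b": "AC", "x": "AA"})
    tree = tree_from("[&R] (a:1,b:1,c:1);", tmp_path)
    with pytest.raises(ValueError, match="missing"):
        scale_tree(tree, g)


def test_scale_tree_simulation_recovers_slope(small_frame):
    import dendropy

    from cladecall.simulate import _refresh_support

    tree = dendropy.Tree(small_frame.tree)
    _refresh_support(tree)
    phylo = scale_tree(tree, small_frame.genotypes)
    assert phylo.scale_unit == "SNVs"
    assert phylo.pearson_r > 0.9
    assert phylo.slope == pytest.approx(1.0, rel=0.10)


def test_midpoint_rooting_applied(tmp_path):
    tree = tree_from("(a:1,b:8,(c:1,d:1):4);", tmp_path)   # unrooted input
    assert tree.is_rooted
    assert {lf.taxon.label for lf in tree.leaf_node_iter()} == {"a", "b", "c", "d"}


# ---------------------------------------------------------------------------
# Dereplication

def brute_dbscan_clusters(d, eps, min_samples):
    """Independent oracle: clusters = eps-components of core points."""
    n = d.shape[0]
    core = [i for i in range(n) if int((d[i] <= eps).sum()) >= min_samples]
    labels = {}
    cid = 0
    for seed in core:
        if seed in labels:
            continue
        stack, comp = [seed], set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            labels[i] = cid
            if i in core:
                for j in range(n):
                    if d[i, j] <= eps and j not in comp:
                        stack.append(j)
        cid += 1
    clusters = {}
    for i, c in labels.items():
        clusters.setdefault(c, set()).add(i)
    noise = set(range(n)) - set(labels)
    return sorted(map(frozenset, clusters.values())), noise


def spaced_genotypes(cluster_sizes, intra=50, inter=2000, seed=0):
    """Genomes in blocks; within-block distance ~2*intra, between >> eps."""
    rng = np.random.default_rng(seed)
    n = sum(cluster_sizes)
    P = inter * len(cluster_sizes) + intra * n + 100
    base = rng.integers(0, 4, P).astype(np.uint8)
    rows, ids = [], []
    pos_cursor = 0
    g_idx = 0
    for b, size in enumerate(cluster_sizes):
        block = base.copy()
        block_sites = np.arange(pos_cursor, pos_cursor + inter)
        block[block_sites] = (block[block_sites] + 1) % 4
        pos_cursor += inter
        for k in range(size):
            row = block.copy()
            sites = np.arange(pos_cursor, pos_cursor + intra)
            row[sites] = (row[sites] + 1) % 4
            pos_cursor += intra
            rows.append(row)
            ids.append(f"g{g_idx:02d}")
            g_idx += 1
    return GenotypeMatrix(ids, np.arange(1, P + 1), np.stack(rows))


def test_dereplicate_pair_within_epsilon():
    g = spaced_genotypes([2], intra=50)     # two genomes 100 SNVs apart
    reps = dereplicate_genomes(g, epsilon=500)
    assert len(reps) == 1


def test_dereplicate_all_singletons():
    g = spaced_genotypes([1, 1, 1], intra=400)  # pairwise distances > 500
    reps = dereplicate_genomes(g, epsilon=500)
    assert reps == g.genome_ids


def test_dereplicate_matches_brute_force_oracle():
    g = spaced_genotypes([3, 2, 4, 1], intra=100, seed=3)
    d = pairwise_hamming(g).astype(float)
    clusters, noise = brute_dbscan_clusters(d, 500, 2)
    reps = dereplicate_genomes(g, epsilon=500)
    assert len(reps) == len(clusters) + len(noise)
    # every cluster contributes exactly one representative
    for comp in clusters:
        assert sum(1 for r in reps if g.genome_ids.index(r) in comp) == 1
    for i in noise:
        assert g.genome_ids[i] in reps


def test_dereplicate_representative_by_coverage():
    g = spaced_genotypes([3], intra=50)
    cov = {"g00": 10.0, "g01": 99.0, "g02": 10.0}
    assert dereplicate_genomes(g, median_coverage=cov) == ["g01"]
    # tie -> lexicographic
    assert dereplicate_genomes(g) == ["g00"]


# ---------------------------------------------------------------------------
# Candidate clades

NESTED_NEWICK = (
    "[&R] ((((a:10,b:10,c:10)0.9:1500,(d:10,e:10,f:10,g:10)0.75:1500,"
    "(h:10,i:10,j:10,k:10)0.9:1000)0.9:1200,l:10)0.8:500,(m:10,n:10)0.9:400);"
)


def nested_phylo(tmp_path):
    tree = tree_from(NESTED_NEWICK, tmp_path)
    return ScaledPhylogeny(tree, "SNVs", 1.0, 1.0)


def test_candidate_criteria(tmp_path):
    clades = enumerate_candidate_clades(nested_phylo(tmp_path))
    member_sets = {frozenset(c.members) for c in clades}
    # 3-leaf clade rejected (size); bootstrap exactly 0.75 rejected (strict >)
    assert frozenset("abc") not in member_sets
    assert frozenset("defg") not in member_sets
    # 4 leaves, branch exactly 1000, bootstrap 0.9 -> accepted (>= on length)
    assert frozenset("hijk") in member_sets
    # 11-leaf internal node accepted; root-adjacent groups never candidates
    assert frozenset("abcdefghijk") in member_sets
    assert frozenset("mn") not in member_sets
    assert len(clades) == 2


def test_candidate_requires_snv_units(tmp_path):
    tree = tree_from(NESTED_NEWICK, tmp_path)
    phylo = ScaledPhylogeny(tree, "raw", 1.0, 0.2)
    with pytest.raises(UnscaledTreeError):
        enumerate_candidate_clades(phylo)
    assert enumerate_candidate_clades(phylo, allow_raw_lengths=True)


# ---------------------------------------------------------------------------
# Barcodes

def brute_barcode(members, genotypes, outgroups=None,
                  max_inclade_ambig=0.10, max_outgroup_nonambig=0.10):
    """Exhaustive position-by-position oracle for clade-specific alleles."""
    members = set(members)
    snvs = []
    for j, pos in enumerate(genotypes.positions):
        incl = [
            genotypes.calls[i, j]
            for i, g in enumerate(genotypes.genome_ids) if g in members
        ]
        rest = [
            genotypes.calls[i, j]
            for i, g in enumerate(genotypes.genome_ids) if g not in members
        ]
        non_n = [c for c in incl if c != N_CODE]
        if not non_n or len(set(non_n)) != 1:
            continue
        if not (1 - len(non_n) / len(incl)) < max_inclade_ambig:
            continue
        allele = non_n[0]
        if any(c == allele for c in rest):
            continue
        if outgroups is not None:
            frac = np.mean(outgroups.calls[:, j] != N_CODE)
            if frac > max_outgroup_nonambig:
                continue
        snvs.append((int(pos), int(allele)))
    return snvs


def clade(members):
    return CandidateClade("c1", sorted(members), 2000.0, 0.9)


def test_private_allele_found():
    g = geno({
        "a": "CAAA", "b": "CAAA",       # clade {a,b} private C at pos 1
        "x": "AAAA", "y": "AAAA",
    })
    bc = find_clade_specific_alleles(clade(["a", "b"]), g)
    assert bc.snvs == [(1, 1)]          # position 1, allele C


def test_allele_carried_outside_excluded():
    g = geno({
        "a": "CAAA", "b": "CAAA",
        "x": "CAAA", "y": "AAAA",       # x also carries the C
    })
    bc = find_clade_specific_alleles(clade(["a", "b"]), g)
    assert bc.snvs == []


def test_outgroup_positions_discarded():
    g = geno({"a": "CCAA", "b": "CCAA", "x": "AAAA", "y": "AAAA"})
    og = geno({"o1": "ANNN", "o2": "GNNN"})
    bc = find_clade_specific_alleles(clade(["a", "b"]), g, outgroups=og)
    # position 1 is non-N in 100% of outgroups -> discarded; position 2 kept
    assert bc.snvs == [(2, 1)]


def test_barcode_matches_brute_force_toy():
    rng = np.random.default_rng(4)
    ids = [f"g{i}" for i in range(6)]
    calls = rng.integers(0, 4, size=(6, 20)).astype(np.uint8)
    calls[:3, :6] = 1                   # shared in-clade block
    calls[rng.uniform(size=(6, 20)) < 0.08] = N_CODE
    g = GenotypeMatrix(ids, np.arange(1, 21), calls)
    bc = find_clade_specific_alleles(clade(ids[:3]), g)
    assert bc.snvs == brute_barcode(ids[:3], g)


def test_barcode_correctness_oracle_simulated(small_db, small_frame):
    geno_m = small_frame.genotypes
    pos_idx = {int(p): j for j, p in enumerate(geno_m.positions)}
    for c in small_db.clades:
        members = set(c.members)
        bc = small_db.barcodes[c.clade_id]
        for pos, allele in bc.snvs:
            col = geno_m.calls[:, pos_idx[pos]]
            for i, gid in enumerate(geno_m.genome_ids):
                if gid in members:
                    assert col[i] in (allele, N_CODE)
                else:
                    assert col[i] != allele


def test_nested_barcodes_disjoint(small_db):
    for c1 in small_db.clades:
        for c2 in small_db.clades:
            if c1 is c2 or not set(c1.members) < set(c2.members):
                continue
            s1 = set(small_db.barcodes[c1.clade_id].snvs)
            s2 = set(small_db.barcodes[c2.clade_id].snvs)
            assert not s1 & s2


def test_genome_removal_equals_recomputation(small_frame, small_db):
    geno_m = small_frame.genotypes
    target = small_db.clades[0]
    outsider = next(
        g for g in geno_m.genome_ids if g not in set(target.members)
    )
    reduced = geno_m.subset_genomes(
        [g for g in geno_m.genome_ids if g != outsider]
    )
    bc_new = find_clade_specific_alleles(target, reduced)
    assert bc_new.snvs == brute_barcode(target.members, reduced)
    # removing an outside genome can only relax exclusivity
    assert set(small_db.barcodes[target.clade_id].snvs) <= set(bc_new.snvs)


# ---------------------------------------------------------------------------
# Database assembly and serialization

def tiny_db_inputs(tmp_path):
    newick = (
        "[&R] (((a:10,b:10,c:10,d:10)0.9:2000,"
        "(e:10,f:10,g:10,h:10)0.9:2000)0.9:100,(i:10,j:10)0.9:100);"
    )
    tree = tree_from(newick, tmp_path)
    P = 30
    base = np.zeros((10, P), dtype=np.uint8)
    ids = list("abcdefgh") + ["i", "j"]
    base[:4, :9] = 1                     # clade {a,b,c,d}: 9 private SNVs
    base[4:8, 9:21] = 2                  # clade {e,f,g,h}: 12 private SNVs
    g = GenotypeMatrix(ids, np.arange(1, P + 1), base)
    return ScaledPhylogeny(tree, "SNVs", 1.0, 1.0), g


def test_min_barcode_rule(tmp_path):
    phylo, g = tiny_db_inputs(tmp_path)
    db = build_database(phylo, g, min_branch=1000)
    sets = [frozenset(c.members) for c in db.clades]
    assert sets == [frozenset("efgh")]   # 9-SNV clade removed, 12-SNV kept
    assert db.barcodes[db.clades[0].clade_id].size == 12


def test_empty_database_error(tmp_path):
    phylo, g = tiny_db_inputs(tmp_path)
    with pytest.raises(EmptyDatabaseError):
        build_database(phylo, g, min_branch=1000, min_cssnvs=50)


def test_database_roundtrip(tmp_path, small_db):
    out = tmp_path / "db"
    small_db.save(out)
    loaded = ReferenceDatabase.load(out)
    assert loaded == small_db
    # deterministic rebuild: saving again is byte-identical
    out2 = tmp_path / "db2"
    loaded.save(out2)
    for name in ("params.tsv", "clades.tsv", "barcodes.tsv"):
        assert (out / name).read_bytes() == (out2 / name).read_bytes()


def test_levels_nested(small_db):
    for c in small_db.clades:
        lvl = small_db.levels[c.clade_id]
        n_anc = sum(
            1 for other in small_db.clades
            if set(c.members) < set(other.members)
        )
        assert lvl == n_anc
    # clades at the same level are disjoint
    by_level = {}
    for c in small_db.clades:
        by_level.setdefault(small_db.levels[c.clade_id], []).append(c)
    for cs in by_level.values():
        for i in range(len(cs)):
            for j in range(i + 1, len(cs)):
                assert not set(cs[i].members) & set(cs[j].members)
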