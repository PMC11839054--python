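"""Allele-count input, base calling, and genome/position filtering.

The universal input is a per-sample, per-position table of stranded
nucleotide read counts plus two per-cell quality annotations: a
consensus-quality score (more negative = more confident; sites with a
score above the cutoff are treated as ambiguous) and the fraction of
reads supporting an indel within +/-3 bp of the site.

Coordinates are 1-based inclusive throughout, matching pileup convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

NUCLEOTIDES = "ACGT"
N_CODE = np.uint8(4)
_CODE_TO_CHAR = np.array(list("ACGTN"))
_CHAR_TO_CODE = {c: i for i, c in enumerate("ACGTN")}

#: call_quality value meaning "no consensus-quality information"; it can
#: never exceed any sane quality cutoff, so the quality rule never fires.
CALL_QUALITY_SENTINEL = -1.0e9

_COUNT_COLUMNS = [f"{nuc}_{strand}" for nuc in NUCLEOTIDES for strand in ("fwd", "rev")]
_HEADER = ["sample", "pos"] + _COUNT_COLUMNS + ["call_quality", "indel_frac"]


class CountsFormatError(ValueError):
    """Raised when a counts or pileup file cannot be parsed."""


@dataclass
class AlleleCountsMatrix:
    """Stranded nucleotide counts for samples x positions.

    Attributes
    ----------
    sample_ids : list of str
    positions : 1-based genome coordinates, strictly increasing, shape (P,)
    counts : int64 tensor, shape (S, P, 4, 2) -- [sample, position, ACGT, fwd/rev]
    call_quality : float array (S, P); sentinel = no information
    indel_fraction : float array (S, P) in [0, 1]
    """

    sample_ids: list[str]
    positions: np.ndarray
    counts: np.ndarray
    call_quality: np.ndarray = None
    indel_fraction: np.ndarray = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        S, P = len(self.sample_ids), len(self.positions)
        if self.call_quality is None:
            self.call_quality = np.full((S, P), CALL_QUALITY_SENTINEL)
        if self.indel_fraction is None:
            self.indel_fraction = np.zeros((S, P))
        self.call_quality = np.asarray(self.call_quality, dtype=float)
        self.indel_fraction = np.asarray(self.indel_fraction, dtype=float)
        self.validate()

    def validate(self) -> None:
        S, P = len(self.sample_ids), len(self.positions)
        if self.counts.shape != (S, P, 4, 2):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{S} samples x {P} positions"
            )
        if self.call_quality.shape != (S, P) or self.indel_fraction.shape != (S, P):
            raise ValueError("quality/indel annotation shapes inconsistent with counts")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")
        if P and ((self.positions[1:] <= self.positions[:-1]).any() or self.positions[0] < 1):
            raise ValueError("positions must be strictly increasing and 1-based")
        bad = (self.indel_fraction < 0) | (self.indel_fraction > 1)
        if bad.any():
            raise ValueError("indel_fraction outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def depth(self) -> np.ndarray:
        """Total read depth per sample x position (all alleles, both strands)."""
        return self.counts.sum(axis=(2, 3))

    def allele_depth(self) -> np.ndarray:
        """Per-allele depth (strands summed), shape (S, P, 4)."""
        return self.counts.sum(axis=3)

    def subset(self, sample_idx=None, position_idx=None) -> "AlleleCountsMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        pi = np.arange(self.n_positions) if position_idx is None else np.asarray(position_idx)
        return AlleleCountsMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            positions=self.positions[pi],
            counts=self.counts[np.ix_(si, pi)],
            call_quality=self.call_quality[np.ix_(si, pi)],
            indel_fraction=self.indel_fraction[np.ix_(si, pi)],
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AlleleCountsMatrix)
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.counts, other.counts)
            and np.allclose(self.call_quality, other.call_quality)
            and np.allclose(self.indel_fraction, other.indel_fraction)
        )


@dataclass
class GenotypeMatrix:
    """Filtered base calls for reference genomes at variable positions.

    ``calls`` holds uint8 codes 0..3 for A,C,G,T and 4 for ambiguous (N).
    """

    genome_ids: list[str]
    positions: np.ndarray
    calls: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        if self.calls.shape != (len(self.genome_ids), len(self.positions)):
            raise ValueError("calls shape inconsistent with genome_ids/positions")
        if (self.calls > 4).any():
            raise ValueError("invalid call codes (expected 0..4)")

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def row(self, genome_id: str) -> np.ndarray:
        return self.calls[self.genome_ids.index(genome_id)]

    def as_characters(self) -> np.ndarray:
        return _CODE_TO_CHAR[self.calls]

    def subset_genomes(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.genome_ids.index(g) for g in keep]
        return GenotypeMatrix(list(keep), self.positions, self.calls[idx])

    def to_tsv(self, path) -> None:
        chars = self.as_characters()
        with open(path, "w") as fh:
            fh.write("genome\t" + "\t".join(str(p) for p in self.positions) + "\n")
            for gid, row in zip(self.genome_ids, chars):
                fh.write(gid + "\t" + "\t".join(row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            positions = np.array([int(p) for p in header[1:]], dtype=np.int64)
            gids, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                gids.append(parts[0])
                rows.append([_CHAR_TO_CODE[c] for c in parts[1:]])
        return cls(gids, positions, np.array(rows, dtype=np.uint8))

    def to_fasta(self, path) -> None:
        """Export calls as aligned FASTA (variable positions only)."""
        chars = self.as_characters()
        with open(path, "w") as fh:
            for gid, row in zip(self.genome_ids, chars):
                fh.write(f">{gid}\n{''.join(row)}\n")


# ---------------------------------------------------------------------------
# Native table I/O

def write_counts(m: AlleleCountsMatrix, path) -> None:
    """Write the native TSV counts table (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for s, sid in enumerate(m.sample_ids):
            for p, pos in enumerate(m.positions):
                cells = [sid, str(pos)]
                cells += [str(int(m.counts[s, p, nuc, strand]))
                          for nuc in range(4) for strand in range(2)]
                cells.append(repr(float(m.call_quality[s, p])))
                cells.append(repr(float(m.indel_fraction[s, p])))
                fh.write("\t".join(cells) + "\n")


def read_counts(path, format: str = "native-table") -> AlleleCountsMatrix:
    """Read an allele-count file.

    ``format`` is ``"native-table"`` (the TSV written by :func:`write_counts`)
    or ``"pileup-text"`` (plain-text samtools mpileup output, one sample).
    """
    if format == "pileup-text":
        return read_pileup(path)
    if format != "native-table":
        raise ValueError(f"unknown counts format: {format!r}")

    per_sample: dict[str, dict[int, tuple]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header:
            raise CountsFormatError(f"{path}: empty counts file")
        if header.rstrip("\n").split("\t") != _HEADER:
            raise CountsFormatError(f"{path}: line 1: unrecognized header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_HEADER):
                raise CountsFormatError(
                    f"{path}: line {lineno}: expected {len(_HEADER)} columns, "
                    f"got {len(parts)}"
                )
            try:
                sid = parts[0]
                pos = int(parts[1])
                cnts = tuple(int(v) for v in parts[2:10])
                cq = float(parts[10])
                indf = float(parts[11])
            except ValueError as exc:
                raise CountsFormatError(f"{path}: line {lineno}: {exc}") from None
            if sid not in per_sample:
                per_sample[sid] = {}
                order.append(sid)
            per_sample[sid][pos] = (cnts, cq, indf)
    if not per_sample:
        raise CountsFormatError(f"{path}: no data rows")

    pos_sets = {sid: tuple(sorted(d)) for sid, d in per_sample.items()}
    ref = pos_sets[order[0]]
    for sid, ps in pos_sets.items():
        if ps != ref:
            raise CountsFormatError(
                f"{path}: inconsistent position sets across samples "
                f"({order[0]!r} vs {sid!r})"
            )
    positions = np.array(ref, dtype=np.int64)
    S, P = len(order), len(positions)
    counts = np.zeros((S, P, 4, 2), dtype=np.int64)
    cq = np.full((S, P), CALL_QUALITY_SENTINEL)
    indf = np.zeros((S, P))
    for s, sid in enumerate(order):
        for p, pos in enumerate(ref):
            cnts, q, f = per_sample[sid][pos]
            counts[s, p] = np.array(cnts).reshape(4, 2)
            cq[s, p] = q
            indf[s, p] = f
    return AlleleCountsMatrix(order, positions, counts, cq, indf)


# ---------------------------------------------------------------------------
# Plain-text pileup parsing (optional single-sample input path)

def _parse_pileup_bases(bases: str, ref: str, lineno: int, path) -> tuple[np.ndarray, int]:
    """Decode one mpileup read-bases string into stranded ACGT counts.

    Returns (counts[4, 2], n_indel_reads). Uppercase/'.' are forward strand,
    lowercase/',' reverse. Indel sequences (+N.../-N...) count the anchoring
    read as indel-supporting.
    """
    counts = np.zeros((4, 2), dtype=np.int64)
    n_indel = 0
    ref_code = _CHAR_TO_CODE.get(ref.upper(), 4)
    i = 0
    while i < len(bases):
        c = bases[i]
        if c == "^":                       # read start; next char is mapq
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":                      # indel: [+-]N<seq>
            j = i + 1
            while j < len(bases) and bases[j].isdigit():
                j += 1
            try:
                length = int(bases[i + 1:j])
            except ValueError:
                raise CountsFormatError(
                    f"{path}: line {lineno}: malformed indel field") from None
            i = j + length
            n_indel += 1
            continue
        if c in ".,":
            if ref_code < 4:
                counts[ref_code, 0 if c == "." else 1] += 1
            i += 1
            continue
        if c.upper() in _CHAR_TO_CODE and c.upper() != "N":
            code = _CHAR_TO_CODE[c.upper()]
            if code < 4:
                counts[code, 0 if c.isupper() else 1] += 1
            i += 1
            continue
        if c in "*<>nN":                   # deletion placeholder / refskip / N
            i += 1
            continue
        raise CountsFormatError(f"{path}: line {lineno}: unexpected pileup symbol {c!r}")
    return counts, n_indel


def read_pileup(path, indel_window: int = 3) -> AlleleCountsMatrix:
    """Parse plain-text samtools mpileup output into a one-sample matrix.

    ``indel_fraction`` at a position is the maximum per-position indel read
    fraction within +/-``indel_window`` bp.  ``call_quality`` is set to the
    sentinel (the pileup text does not carry a consensus-quality score).
    """
    positions, tensors, indels, depths = [], [], [], []
    with open(path) as fh:
        any_line = False
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            any_line = True
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise CountsFormatError(
                    f"{path}: line {lineno}: expected >=5 pileup columns, got {len(parts)}")
            try:
                pos = int(parts[1])
                depth = int(parts[3])
            except ValueError as exc:
                raise CountsFormatError(f"{path}: line {lineno}: {exc}") from None
            cnt, n_indel = _parse_pileup_bases(parts[4], parts[2], lineno, path)
            positions.append(pos)
            tensors.append(cnt)
            indels.append(n_indel)
            depths.append(max(depth, 1))
    if not any_line:
        raise CountsFormatError(f"{path}: empty pileup file")

    order = np.argsort(positions)
    positions = np.array(positions, dtype=np.int64)[order]
    tensor = np.array(tensors, dtype=np.int64)[order][None, :]
    indels = np.array(indels, dtype=float)[order]
    depths = np.array(depths, dtype=float)[order]

    frac = np.zeros(len(positions))
    for i, pos in enumerate(positions):
        window = np.abs(positions - pos) <= indel_window
        frac[i] = np.max(indels[window] / depths[window])
    frac = np.clip(frac, 0.0, 1.0)
    return AlleleCountsMatrix(
        ["pileup"], positions, tensor, indel_fraction=frac[None, :])


# ---------------------------------------------------------------------------
# Base calling and filtering

def call_bases(
    m: AlleleCountsMatrix,
    maf_min: float = 0.85,
    strand_min: int = 3,
    fq_max: float = -30.0,
    indel_max: float = 1.0 / 3.0,
) -> np.ndarray:
    """Call the major allele per sample x position, with ambiguity rules.

    A call is the major (most-supported) allele unless any rule fires, in
    which case it is N (code 4):

    * call_quality above ``fq_max`` (less confident than the cutoff);
    * either strand's major-allele depth below ``strand_min``;
    * major allele frequency below ``maf_min``;
    * indel-supporting read fraction strictly above ``indel_max``.

    Rules are independent and OR-combined; all-zero counts yield N.
    """
    per_allele = m.allele_depth()                       # (S, P, 4)
    total = per_allele.sum(axis=2)                      # (S, P)
    major = per_allele.argmax(axis=2)                   # ties -> lowest code
    major_depth = np.take_along_axis(per_allele, major[..., None], axis=2)[..., 0]

    s_idx = np.arange(m.n_samples)[:, None]
    p_idx = np.arange(m.n_positions)[None, :]
    major_fwd = m.counts[s_idx, p_idx, major, 0]
    major_rev = m.counts[s_idx, p_idx, major, 1]

    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(total > 0, major_depth / np.maximum(total, 1), 0.0)

    ambiguous = (
        (total == 0)
        | (m.call_quality > fq_max)
        | (major_fwd < strand_min)
        | (major_rev < strand_min)
        | (maf < maf_min)
        | (m.indel_fraction > indel_max)
    )
    calls = major.astype(np.uint8)
    calls[ambiguous] = N_CODE
    return calls


def filter_genomes_by_coverage(
    m: AlleleCountsMatrix, min_median_cov: float = 8.0
) -> np.ndarray:
    """Indices of genomes whose median per-position depth is >= the cutoff."""
    med = np.median(m.depth(), axis=1)
    return np.flatnonzero(med >= min_median_cov)


def filter_positions(
    m: AlleleCountsMatrix,
    calls: np.ndarray,
    max_n_frac: float = 0.10,
    min_median_cov: float = 5.0,
    copy_number_mult: float = 2.0,
) -> np.ndarray:
    """Indices of positions passing the cross-genome filters.

    A position is dropped when more than ``max_n_frac`` of genomes call N
    there, when its median cross-genome depth is below ``min_median_cov``,
    or when that median exceeds ``copy_number_mult`` times the genome-wide
    median over retained positions (a copy-number proxy; iterated to a
    fixed point so the filter is idempotent).
    """
    depth = m.depth()
    n_frac = (calls == N_CODE).mean(axis=0)
    pos_med = np.median(depth, axis=0)
    ok = (n_frac <= max_n_frac) & (pos_med >= min_median_cov)
    # copy-number rule relative to the median over currently-retained
    # positions, repeated until stable
    while True:
        if not ok.any():
            break
        core_med = np.median(pos_med[ok])
        new_ok = ok & (pos_med <= copy_number_mult * core_med)
        if new_ok.sum() == ok.sum():
            break
        ok = new_ok
    return np.flatnonzero(ok)


def filter_genomes_by_ambiguity(
    calls: np.ndarray, position_idx: np.ndarray, max_ambig_frac: float = 0.10
) -> np.ndarray:
    """Indices of genomes with <= ``max_ambig_frac`` N among retained positions."""
    if len(position_idx) == 0:
        return np.arange(calls.shape[0])
    sub = calls[:, position_idx]
    return np.flatnonzero((sub == N_CODE).mean(axis=1) <= max_ambig_frac)


def filter_genomes(
    m: AlleleCountsMatrix,
    calls: np.ndarray,
    min_median_cov: float = 8.0,
    max_ambig_frac: float = 0.10,
    position_idx: np.ndarray | None = None,
) -> list[str]:
    """Retained genome ids after the coverage and post-filter ambiguity rules."""
    cov_idx = filter_genomes_by_coverage(m, min_median_cov)
    if position_idx is None:
        position_idx = np.arange(m.n_positions)
    amb_idx = filter_genomes_by_ambiguity(calls, position_idx, max_ambig_frac)
    keep = sorted(set(cov_idx) & set(amb_idx))
    return [m.sample_ids[i] for i in keep]


def build_genotype_matrix(
    m: AlleleCountsMatrix,
    maf_min: float = 0.85,
    strand_min: int = 3,
    fq_max: float = -30.0,
    indel_max: float = 1.0 / 3.0,
    min_genome_cov: float = 8.0,
    min_pos_cov: float = 5.0,
    max_pos_n_frac: float = 0.10,
    copy_number_mult: float = 2.0,
    max_genome_n_frac: float = 0.10,
    variable_only: bool = True,
) -> GenotypeMatrix:
    """Full filtering pipeline: counts -> clean genotype matrix.

    Order of operations: base calling; genome coverage filter; position
    filters (on retained genomes); genome ambiguity filter at retained
    positions. When ``variable_only``, monomorphic positions are dropped
    at the end.
    """
    calls = call_bases(m, maf_min, strand_min, fq_max, indel_max)

    g_idx = filter_genomes_by_coverage(m, min_genome_cov)
    if len(g_idx) == 0:
        raise EmptyDatabaseError("all genomes failed the median-coverage filter")
    m2 = m.subset(sample_idx=g_idx)
    calls2 = calls[g_idx]

    p_idx = filter_positions(m2, calls2, max_pos_n_frac, min_pos_cov, copy_number_mult)
    a_idx = filter_genomes_by_ambiguity(calls2, p_idx, max_genome_n_frac)
    if len(a_idx) == 0:
        raise EmptyDatabaseError("all genomes failed the ambiguity filter")

    final_calls = calls2[np.ix_(a_idx, p_idx)]
    positions = m2.positions[p_idx]
    gids = [m2.sample_ids[i] for i in a_idx]

    if variable_only and final_calls.size:
        non_n = final_calls != N_CODE
        variable = np.zeros(final_calls.shape[1], dtype=bool)
        for j in range(final_calls.shape[1]):
            vals = np.unique(final_calls[non_n[:, j], j])
            variable[j] = len(vals) > 1
        final_calls = final_calls[:, variable]
        positions = positions[variable]
    return GenotypeMatrix(gids, positions, final_calls)


class EmptyDatabaseError(RuntimeError):
    """No genomes or clades survive filtering; a database cannot be built."""


def encode_calls(chars: Iterable[str]) -> np.ndarray:
    """Convert an iterable of 'A','C','G','T','N' into uint8 codes."""
    return np.array([_CHAR_TO_CODE[c.upper()] for c in chars], dtype=np.uint8)


def read_fasta_lengths(path) -> dict[str, int]:
    """Sequence lengths from a FASTA reference assembly (id -> length)."""
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def validate_positions_against_assembly(m: AlleleCountsMatrix, fasta_path) -> None:
    """Check that coordinates fit inside the (single-contig) assembly."""
    lengths = read_fasta_lengths(fasta_path)
    if not lengths:
        raise CountsFormatError(f"{fasta_path}: no sequences")
    total = sum(lengths.values())
    if m.n_positions and m.positions[-1] > total:
        raise ValueError(
            f"position {m.positions[-1]} exceeds assembly length {total}"
        )
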