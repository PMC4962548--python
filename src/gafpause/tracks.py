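"""Genomic interval containers, per-base coverage tracks and standard-format I/O.

Everything downstream of this module works on three containers:

* :class:`GenomeSequence` -- per-chromosome nucleotide strings (A/C/G/T/N).
* :class:`FragmentSet`    -- read or MNase-protected fragments as 0-based
  half-open intervals, grouped by chromosome.
* :class:`CoverageTrack`  -- one non-negative value per base pair, either raw
  counts or depth-normalized to reads-per-million.

Coordinates are 0-based half-open throughout; GFF3 input (1-based closed) is
converted on load.  Coverage construction is deliberately strand-agnostic:
strand only enters when a window is mapped TSS-relative (see
:func:`window_values`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CoverageMode = Literal["full_fragment", "midpoint", "five_prime"]


def reverse_complement(seq: str) -> str:
    """Reverse-complement an A/C/G/T/N string."""
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """Per-chromosome nucleotide sequence with length bookkeeping."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            extra = set(seq.upper()) - VALID_BASES
            if extra:
                raise ValueError(
                    f"chromosome {chrom!r} contains invalid bases {sorted(extra)}"
                )
            self.sequences[chrom] = seq.upper()

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.sequences)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self.sequences[chrom]) or start > end:
            raise ValueError(f"window [{start},{end}) outside {chrom}")
        return self.sequences[chrom][start:end]

    def mirrored(self) -> "GenomeSequence":
        """Reverse-complement every chromosome (coordinate p -> L-1-p)."""
        return GenomeSequence({c: reverse_complement(s) for c, s in self.sequences.items()})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no sequences found in {path}")
        return cls(seqs)

    def to_fasta(self, path: str | Path) -> None:
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(s), id=c, description="") for c, s in sorted(self.sequences.items())]
        SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One annotated gene with a strand-aware TSS.

    ``tss`` is the first transcribed base: ``start`` on the plus strand and
    ``end - 1`` on the minus strand.  ``n_tss_annotated`` carries how many
    distinct start sites the annotation lists for the locus; the selection
    stage keeps single-TSS genes only.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_tss_annotated: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.n_tss_annotated < 1:
            raise ValueError(f"gene {self.gene_id}: n_tss_annotated must be >= 1")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start

    def mirrored(self, chrom_length: int) -> "GeneModel":
        return GeneModel(
            gene_id=self.gene_id,
            chrom=self.chrom,
            start=chrom_length - self.end,
            end=chrom_length - self.start,
            strand="-" if self.strand == "+" else "+",
            n_tss_annotated=self.n_tss_annotated,
        )


def load_genes(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Load gene models from BED6/BED12 or GFF3.

    BED: the score column carries the annotated-TSS count (0 is read as 1).
    GFF3: ``gene`` features; the TSS count is the number of distinct 5' ends
    among child transcript features when any are present.

    Genes are returned sorted by (chrom, start); duplicate gene ids raise.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "gff3" if suffix in (".gff", ".gff3") else "bed"
    format = format.lower()
    if format in ("bed", "bed6", "bed12"):
        genes = _load_genes_bed(path)
    elif format == "gff3":
        genes = _load_genes_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")

    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _load_genes_bed(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(fields)}")
            try:
                chrom, start, end, name, score, strand = fields[:6]
                start_i, end_i = int(start), int(end)
                n_tss = max(1, int(float(score)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line ({exc})") from None
            try:
                genes.append(GeneModel(name, chrom, start_i, end_i, strand, n_tss))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return genes


def _load_genes_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        children = list(db.children(feat, featuretype=("mRNA", "transcript")))
        if children:
            tss_set = {c.start if c.strand == "+" else c.end for c in children}
            n_tss = len(tss_set)
        else:
            n_tss = 1
        # GFF3 is 1-based closed
        genes.append(GeneModel(feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand, n_tss))
    return genes


def write_genes_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{g.n_tss_annotated}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

@dataclass
class FragmentSet:
    """Genomic intervals for one sample, grouped by chromosome.

    ``intervals`` maps chromosome name to an (n, 2) int64 array of 0-based
    half-open [start, end) rows.  ``total_count`` always equals the number of
    stored records.
    """

    sample_id: str
    condition: str = "WT"
    assay: str = "input"
    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size and not np.all(arr[:, 0] < arr[:, 1]):
                bad = arr[arr[:, 0] >= arr[:, 1]][0]
                raise ValueError(
                    f"{self.sample_id}: fragment {chrom}:{bad[0]}-{bad[1]} has end <= start"
                )
            clean[chrom] = arr
        self.intervals = clean

    @property
    def total_count(self) -> int:
        return int(sum(a.shape[0] for a in self.intervals.values()))

    def records(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self.intervals):
            for s, e in self.intervals[chrom]:
                yield chrom, int(s), int(e)

    def lengths(self) -> np.ndarray:
        if not self.intervals:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([a[:, 1] - a[:, 0] for a in self.intervals.values()])

    def midpoints(self, chrom: str) -> np.ndarray:
        """floor((start + end) / 2) per fragment on one chromosome."""
        arr = self.intervals.get(chrom)
        if arr is None or not arr.size:
            return np.empty(0, dtype=np.int64)
        return (arr[:, 0] + arr[:, 1]) // 2

    def subsample(self, fraction: float, seed: int) -> "FragmentSet":
        rng = np.random.default_rng(seed)
        out = {}
        for chrom in sorted(self.intervals):
            arr = self.intervals[chrom]
            keep = rng.random(arr.shape[0]) < fraction
            out[chrom] = arr[keep]
        return FragmentSet(f"{self.sample_id}:sub{fraction}", self.condition, self.assay, out)

    def tile(self, times: int) -> "FragmentSet":
        """Replicate every record ``times`` times (global depth rescaling)."""
        out = {c: np.repeat(a, times, axis=0) for c, a in self.intervals.items()}
        return FragmentSet(f"{self.sample_id}:x{times}", self.condition, self.assay, out)

    def mirrored(self, chrom_lengths: dict[str, int]) -> "FragmentSet":
        out = {}
        for chrom, arr in self.intervals.items():
            L = chrom_lengths[chrom]
            flipped = np.column_stack([L - arr[:, 1], L - arr[:, 0]])
            out[chrom] = flipped
        return FragmentSet(self.sample_id + ":mirror", self.condition, self.assay, out)


def load_fragments(
    path: str | Path,
    format: str | None = None,
    sample_id: str | None = None,
    condition: str = "WT",
    assay: str = "input",
) -> FragmentSet:
    """Load a :class:`FragmentSet` from BED, BEDPE or SAM/BAM.

    BEDPE mates must share a chromosome; the fragment is the template extent
    (min start to max end).  SAM/BAM uses properly paired reads: the fragment
    is the template span taken from the leftmost mate's TLEN.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if format is None:
        suffix = path.suffix.lower()
        format = {".bedpe": "bedpe", ".sam": "sam", ".bam": "bam"}.get(suffix, "bed")
    format = format.lower()

    per_chrom: dict[str, list[tuple[int, int]]] = {}

    def add(chrom: str, s: int, e: int, where: str) -> None:
        if e <= s:
            raise ValueError(f"{where}: fragment end {e} <= start {s}")
        per_chrom.setdefault(chrom, []).append((s, e))

    if format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                if len(f) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
                add(f[0], int(f[1]), int(f[2]), f"{path}:{lineno}")
    elif format == "bedpe":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                f = line.split()
                if len(f) < 6:
                    raise ValueError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
                c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
                if c1 != c2:
                    raise ValueError(f"{path}:{lineno}: BEDPE mates on different chromosomes")
                add(c1, min(s1, s2), max(e1, e2), f"{path}:{lineno}")
    elif format in ("sam", "bam"):
        import pysam

        mode = "rb" if format == "bam" else "r"
        with pysam.AlignmentFile(str(path), mode) as af:
            for read in af:
                if read.is_unmapped or not read.is_proper_pair:
                    continue
                if read.template_length <= 0:  # keep leftmost mate only
                    continue
                add(
                    read.reference_name,
                    read.reference_start,
                    read.reference_start + read.template_length,
                    f"{path}:{read.query_name}",
                )
    else:
        raise ValueError(f"unknown fragment format {format!r}")

    frags = FragmentSet(
        sample_id,
        condition,
        assay,
        {c: np.array(v, dtype=np.int64) for c, v in per_chrom.items()},
    )
    if frags.total_count == 0:
        log.warning("no fragments loaded from %s", path)
    return frags


def write_fragments_bed(frags: FragmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in frags.records():
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Coverage tracks
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """One float per base pair per chromosome.

    ``scale`` is either ``"raw"`` (counts) or ``"per_million"``
    (counts x 1e6 / total_count of the source sample).
    """

    data: dict[str, np.ndarray]
    scale: str = "raw"
    total_count: int = 0

    def __post_init__(self) -> None:
        for chrom, arr in self.data.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.size and arr.min() < 0:
                raise ValueError(f"negative coverage on {chrom}")
            self.data[chrom] = arr

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.data[chrom][start:end]

    def total_mass(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))


def build_coverage(
    frags: FragmentSet,
    chrom_lengths: dict[str, int],
    mode: CoverageMode = "full_fragment",
) -> CoverageTrack:
    """Accumulate fragments into a raw per-base track.

    ``full_fragment`` adds 1 over every covered base; ``midpoint`` adds 1 at
    floor((start+end)/2); ``five_prime`` adds 1 at the fragment start (the
    reference-strand 5' end; fragments carry no strand of their own).
    """
    data = {c: np.zeros(L, dtype=np.float64) for c, L in chrom_lengths.items()}
    for chrom, arr in frags.intervals.items():
        if chrom not in chrom_lengths:
            raise ValueError(f"fragment chromosome {chrom!r} not in chromosome table")
        if not arr.size:
            continue
        L = chrom_lengths[chrom]
        if arr[:, 1].max() > L or arr[:, 0].min() < 0:
            bad = arr[(arr[:, 1] > L) | (arr[:, 0] < 0)][0]
            raise ValueError(
                f"fragment {chrom}:{bad[0]}-{bad[1]} extends beyond chromosome length {L}"
            )
        vec = data[chrom]
        if mode == "full_fragment":
            # difference-array pileup
            diff = np.zeros(L + 1, dtype=np.float64)
            np.add.at(diff, arr[:, 0], 1.0)
            np.add.at(diff, arr[:, 1], -1.0)
            vec += np.cumsum(diff[:-1])
        elif mode == "midpoint":
            np.add.at(vec, (arr[:, 0] + arr[:, 1]) // 2, 1.0)
        elif mode == "five_prime":
            np.add.at(vec, arr[:, 0], 1.0)
        else:
            raise ValueError(f"unknown coverage mode {mode!r}")
    return CoverageTrack(data, scale="raw", total_count=frags.total_count)


def normalize_per_million(track: CoverageTrack) -> CoverageTrack:
    """Rescale a raw track to reads-per-million of the source sample."""
    if track.scale == "per_million":
        return track
    if track.total_count <= 0:
        raise ValueError("cannot depth-normalize a track from an empty sample")
    factor = 1e6 / track.total_count
    data = {c: a * factor for c, a in track.data.items()}
    return CoverageTrack(data, scale="per_million", total_count=track.total_count)


@dataclass
class EnrichmentProfile:
    """Per-base ChIP/input fold enrichment (dimensionless)."""

    data: dict[str, np.ndarray]
    pseudocount: float = 0.5

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}


def enrichment_over_input(
    chip: CoverageTrack, input_track: CoverageTrack, pseudocount: float = 0.5
) -> EnrichmentProfile:
    """(chip + pc) / (input + pc) per base, both tracks per-million."""
    if chip.scale != "per_million" or input_track.scale != "per_million":
        raise ValueError("enrichment requires per_million tracks")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if set(chip.data) != set(input_track.data):
        raise ValueError("ChIP and input tracks cover different chromosome sets")
    data = {}
    for chrom in chip.data:
        if len(chip.data[chrom]) != len(input_track.data[chrom]):
            raise ValueError(f"length mismatch on {chrom}")
        data[chrom] = (chip.data[chrom] + pseudocount) / (input_track.data[chrom] + pseudocount)
    return EnrichmentProfile(data, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# bedGraph round trip
# ---------------------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write non-zero constant runs as bedGraph records."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            if not vec.size:
                continue
            change = np.flatnonzero(np.diff(vec)) + 1
            bounds = np.concatenate([[0], change, [len(vec)]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = float(vec[s])
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def read_bedgraph(
    path: str | Path, chrom_lengths: dict[str, int], scale: str = "raw", total_count: int = 0
) -> CoverageTrack:
    data = {c: np.zeros(L, dtype=np.float64) for c, L in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = f[0], int(f[1]), int(f[2]), float(f[3])
            data[chrom][s:e] = v
    return CoverageTrack(data, scale=scale, total_count=total_count)


# ---------------------------------------------------------------------------
# TSS-relative windows
# ---------------------------------------------------------------------------

def relative_window(gene: GeneModel, r0: int, r1: int) -> tuple[int, int]:
    """Genomic [start, end) covering TSS-relative [r0, r1) for ``gene``.

    Plus strand: [tss + r0, tss + r1).  Minus strand the window mirrors:
    relative position r sits at genomic tss - r, so the span is
    [tss - r1 + 1, tss - r0 + 1).
    """
    t = gene.tss
    if gene.strand == "+":
        return t + r0, t + r1
    return t - r1 + 1, t - r0 + 1


def window_values(
    track: CoverageTrack,
    gene: GeneModel,
    r0: int,
    r1: int,
    oob: str = "error",
) -> np.ndarray | None:
    """Strand-aware track values over TSS-relative [r0, r1).

    Element i corresponds to relative position r0 + i; for minus-strand
    genes the genomic slice is reversed.  ``oob`` controls windows that
    leave the chromosome: ``"error"`` raises, ``"drop"`` returns None,
    ``"truncate"`` clips (positions off the end are simply absent, so the
    returned vector may be shorter than r1 - r0).
    """
    gs, ge = relative_window(gene, r0, r1)
    L = len(track.data[gene.chrom])
    if gs < 0 or ge > L:
        if oob == "error":
            raise ValueError(
                f"gene {gene.gene_id}: window [{gs},{ge}) outside chromosome of length {L}"
            )
        if oob == "drop":
            return None
        gs, ge = max(gs, 0), min(ge, L)
        log.info("gene %s: window truncated to [%d,%d)", gene.gene_id, gs, ge)
    vals = track.data[gene.chrom][gs:ge]
    return vals if gene.strand == "+" else vals[::-1]


def relative_positions(gene: GeneModel, positions: np.ndarray) -> np.ndarray:
    """Map genomic base positions to TSS-relative coordinates for ``gene``."""
    positions = np.asarray(positions, dtype=np.int64)
    if gene.strand == "+":
        return positions - gene.tss
    return gene.tss - positions
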