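"""Annotated circular mitogenomes and feature arithmetic.

Insect mitogenomes are compact circles (~15 kb) carrying 13 protein-coding
genes (PCGs), 22 tRNAs, 2 rRNAs and one AT-rich control region.  This module
models such an annotation with 1-based inclusive coordinates on the majority
(J) strand — the convention used in published mitogenome feature tables —
and provides the feature arithmetic a comparative study needs: sizes,
intergenic spacers (IGS, negative = overlap), genome-length reconstruction
and start/stop codon verification under the invertebrate mitochondrial
genetic code (translation table 5).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

CATEGORIES = ("PCG", "tRNA", "rRNA", "control-region")
STRANDS = ("J", "N")

#: stop codons of the invertebrate mitochondrial code, plus the incomplete
#: forms completed to TAA by post-transcriptional polyadenylation
INCOMPLETE_STOPS = ("T", "TA")


class AnnotationError(ValueError):
    """Raised when an annotation violates the coordinate conventions."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature in J-strand 1-based inclusive coordinates.

    ``stop < start`` is only legal for the single feature allowed to wrap
    the circular origin.  N-strand features keep J-strand coordinates;
    sequence extraction reverse-complements.
    """

    name: str
    category: str
    strand: str
    start: int
    stop: int
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise AnnotationError(
                f"{self.name}: category {self.category!r} not in {CATEGORIES}"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.name}: strand must be J or N")
        if self.start < 1 or self.stop < 1:
            raise AnnotationError(f"{self.name}: coordinates are 1-based (>= 1)")

    @property
    def wraps(self) -> bool:
        return self.stop < self.start


@dataclass
class AnnotatedMitogenome:
    """A circular mitogenome: optional sequence plus ordered features.

    ``sequence`` may be ``None`` for coordinate-only annotations (published
    feature tables); then ``length`` must be given explicitly when an
    operation needs it.
    """

    organism: str
    features: list[GeneFeature]
    sequence: Optional[str] = None
    length: Optional[int] = None
    circular: bool = True

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise AnnotationError(f"sequence contains non-ACGTN symbols: {bad}")
            if self.length is None:
                self.length = len(self.sequence)
            elif self.length != len(self.sequence):
                raise AnnotationError("length disagrees with sequence length")
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise AnnotationError("feature names must be unique")
        self.features = sorted(self.features, key=lambda f: f.start)
        wrapping = [f for f in self.features if f.wraps]
        if len(wrapping) > 1:
            raise AnnotationError("at most one feature may wrap the origin")
        # a wrapping feature crosses the origin, so it must be last in order
        if wrapping and wrapping[0] is not self.features[-1]:
            raise AnnotationError(
                f"{wrapping[0].name}: stop < start on a non-origin feature"
            )
        if self.length is not None:
            for f in self.features:
                if f.start > self.length or f.stop > self.length:
                    raise AnnotationError(
                        f"{f.name}: [{f.start},{f.stop}] outside genome "
                        f"of length {self.length}"
                    )

    @property
    def genome_length(self) -> int:
        if self.length is None:
            raise AnnotationError(f"{self.organism}: genome length unknown")
        return self.length

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def pcgs(self) -> list[GeneFeature]:
        return [f for f in self.features if f.category == "PCG"]

    def extract(self, f: GeneFeature) -> str:
        """Coding-strand sequence of a feature (reverse-complemented for N)."""
        if self.sequence is None:
            raise AnnotationError("no sequence attached")
        if f.wraps:
            seg = self.sequence[f.start - 1 :] + self.sequence[: f.stop]
        else:
            seg = self.sequence[f.start - 1 : f.stop]
        if f.strand == "N":
            seg = str(Seq(seg).reverse_complement())
        return seg

    def rotated(self, shift: int) -> "AnnotatedMitogenome":
        """Rotate the circular origin by ``shift`` bases (for invariance tests)."""
        n = self.genome_length

        def rot(pos: int) -> int:
            return (pos - 1 - shift) % n + 1

        feats = [replace(f, start=rot(f.start), stop=rot(f.stop)) for f in self.features]
        seq = None
        if self.sequence is not None:
            seq = self.sequence[shift:] + self.sequence[:shift]
        return AnnotatedMitogenome(
            organism=self.organism, features=feats, sequence=seq, length=n
        )


@dataclass
class IntergenicReport:
    """Spacers between adjacent features in genome order.

    ``boundaries`` holds ``(upstream_name, downstream_name, igs_bp)`` with
    ``igs_bp = downstream.start - upstream.stop - 1``; negative values are
    gene overlaps.  ``terminal_igs`` is the gap between the last feature's
    stop and the circular origin (``genome_length - last_stop``).
    """

    boundaries: list[tuple[str, str, int]] = field(default_factory=list)
    terminal_igs: Optional[int] = None

    @property
    def overlaps(self) -> list[tuple[str, str, int]]:
        return [b for b in self.boundaries if b[2] < 0]

    @property
    def n_overlaps(self) -> int:
        return len(self.overlaps)

    def largest_spacer(self) -> tuple[str, str, int]:
        return max(self.boundaries, key=lambda b: b[2])


def feature_length(f: GeneFeature, genome_length: Optional[int] = None) -> int:
    """Length in bp of a feature; wrapping features need ``genome_length``."""
    if not f.wraps:
        return f.stop - f.start + 1
    if genome_length is None:
        raise AnnotationError(f"{f.name} wraps the origin; genome_length required")
    return (genome_length - f.start + 1) + f.stop


def intergenic_spacers(
    g: AnnotatedMitogenome, terminal_igs: Optional[int] = None
) -> IntergenicReport:
    """Spacer between every adjacent feature pair plus the terminal spacer.

    Features are taken in genome order (the constructor sorts by start; if a
    caller mutated the list, it is re-sorted here with a warning).  When the
    genome length is unknown the terminal spacer may be supplied (published
    tables print it); otherwise it is ``genome_length - last_stop``.
    """
    if len(g.features) < 2:
        raise AnnotationError("need at least 2 features")
    feats = g.features
    if any(feats[i].start > feats[i + 1].start for i in range(len(feats) - 1)):
        logger.warning("features were not sorted by start; sorting internally")
        feats = sorted(feats, key=lambda f: f.start)
    boundaries = []
    for up, down in zip(feats, feats[1:]):
        boundaries.append((up.name, down.name, down.start - up.stop - 1))
    last = feats[-1]
    if terminal_igs is None and g.length is not None:
        terminal_igs = g.genome_length - last.stop
    return IntergenicReport(boundaries=boundaries, terminal_igs=terminal_igs)


def reconstruct_genome_length(
    report: IntergenicReport, last_feature: GeneFeature, first_feature: GeneFeature
) -> int:
    """Genome length from an annotation that covers the full circle.

    Convention: the first feature starts at position 1, so the length is the
    last feature's stop plus the terminal spacer back to the origin.
    """
    if first_feature.start != 1:
        raise AnnotationError(
            f"first feature {first_feature.name} starts at {first_feature.start}, "
            "expected 1 (full-circle convention)"
        )
    if report.terminal_igs is None:
        raise AnnotationError("terminal spacer unknown; cannot close the circle")
    return last_feature.stop + report.terminal_igs


def pcg_length_summary(g: AnnotatedMitogenome) -> dict:
    """Raw and overlap-deduplicated total PCG length.

    The raw sum adds printed per-gene sizes; the deduplicated sum counts each
    genomic position covered by at least one PCG once, so PCG/PCG overlaps
    are not double-counted.  Published totals can differ by a few bp
    depending on which convention a study used; both are reported, neither
    privileged.
    """
    pcgs = g.pcgs()
    raw = sum(feature_length(f, g.length) for f in pcgs)
    covered: set[int] = set()
    for f in pcgs:
        if f.wraps:
            covered.update(range(f.start, g.genome_length + 1))
            covered.update(range(1, f.stop + 1))
        else:
            covered.update(range(f.start, f.stop + 1))
    return {"raw_sum": raw, "dedup_sum": len(covered), "n_pcgs": len(pcgs)}


@dataclass
class CodonCheck:
    gene: str
    observed_start: str
    observed_stop: str
    frame_ok: bool
    matches_annotation: Optional[bool]


def verify_codons(g: AnnotatedMitogenome, table: int = 5) -> list[CodonCheck]:
    """Read each PCG's start/stop codon off the sequence and check the frame.

    Codons are read on the coding strand (N-strand features are
    reverse-complemented).  Incomplete stop codons T / TA — completed to TAA
    by polyadenylation of the mature transcript — are accepted and reported
    as ``"T(incomplete)"`` / ``"TA(incomplete)"``.  A frame length not
    congruent to 0 mod 3 after stop completion is flagged, not fatal.
    """
    code = CodonTable.unambiguous_dna_by_id[table]
    out = []
    for f in g.pcgs():
        seq = g.extract(f)
        start = seq[:3]
        rem = len(seq) % 3
        if rem == 0:
            stop = seq[-3:]
            frame_ok = stop in code.stop_codons
            observed_stop = stop
        else:
            tail = seq[-rem:]
            frame_ok = tail in INCOMPLETE_STOPS
            observed_stop = f"{tail}(incomplete)" if frame_ok else tail
        match: Optional[bool] = None
        if f.start_codon or f.stop_codon:
            match = True
            if f.start_codon and f.start_codon != start:
                match = False
            if f.stop_codon and f.stop_codon not in (
                observed_stop,
                observed_stop.replace("(incomplete)", ""),
            ):
                match = False
        if not frame_ok:
            logger.warning(
                "%s: frame length %d not 0 mod 3 after stop completion",
                f.name,
                len(seq),
            )
        out.append(CodonCheck(f.name, start, observed_stop, frame_ok, match))
    return out


# ---------------------------------------------------------------------------
# I/O: GenBank flat file, FASTA + TSV annotation table
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ("name", "category", "strand", "start", "stop", "start_codon", "stop_codon")

_GENBANK_CATEGORY = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control-region",
    "misc_feature": "control-region",
}


def read_annotated_genome(
    path: str | Path,
    fmt: str = "genbank",
    annotation_path: str | Path | None = None,
    organism: Optional[str] = None,
) -> AnnotatedMitogenome:
    """Read an annotated mitogenome from GenBank or FASTA + TSV.

    TSV dialect: tab-separated columns ``name, category, strand, start,
    stop, start_codon, stop_codon`` (last two optional), ``#`` comments,
    1-based inclusive coordinates.
    """
    path = Path(path)
    if fmt == "genbank":
        record = SeqIO.read(str(path), "genbank")
        feats = []
        for sf in record.features:
            if sf.type not in _GENBANK_CATEGORY:
                continue
            name = (
                sf.qualifiers.get("gene", [None])[0]
                or sf.qualifiers.get("product", [None])[0]
                or sf.type
            )
            feats.append(
                GeneFeature(
                    name=name,
                    category=_GENBANK_CATEGORY[sf.type],
                    strand="J" if sf.location.strand != -1 else "N",
                    start=int(sf.location.start) + 1,  # biopython is 0-based
                    stop=int(sf.location.end),
                )
            )
        return AnnotatedMitogenome(
            organism=organism or record.annotations.get("organism", record.id),
            features=feats,
            sequence=str(record.seq),
        )
    if fmt == "fasta+tsv":
        if annotation_path is None:
            raise ValueError("fasta+tsv requires annotation_path")
        record = SeqIO.read(str(path), "fasta")
        feats, _ = read_annotation_table(annotation_path)
        return AnnotatedMitogenome(
            organism=organism or record.id, features=feats, sequence=str(record.seq)
        )
    raise ValueError(f"unknown format {fmt!r}")


def read_annotation_table(path: str | Path) -> tuple[list[GeneFeature], dict]:
    """Parse a TSV annotation table; returns features and header metadata.

    Header comments of the form ``# key: value`` (e.g. ``terminal_igs``,
    ``organism``) are collected into the metadata dict.
    """
    meta: dict = {}
    feats: list[GeneFeature] = []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip()[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if parts[0] == "name":  # header row
                continue
            if len(parts) < 5:
                raise AnnotationError(f"{path}:{lineno}: expected >=5 columns")
            try:
                start, stop = int(parts[3]), int(parts[4])
            except ValueError as e:
                raise AnnotationError(f"{path}:{lineno}: bad coordinate ({e})") from e
            feats.append(
                GeneFeature(
                    name=parts[0].strip(),
                    category=parts[1].strip(),
                    strand=parts[2].strip(),
                    start=start,
                    stop=stop,
                    start_codon=parts[5].strip() or None if len(parts) > 5 else None,
                    stop_codon=parts[6].strip() or None if len(parts) > 6 else None,
                )
            )
    return feats, meta


def write_annotation_table(
    features: Iterable[GeneFeature], path: str | Path, meta: Optional[dict] = None
) -> None:
    with open(path, "w", newline="") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for f in features:
            w.writerow(
                [f.name, f.category, f.strand, f.start, f.stop,
                 f.start_codon or "", f.stop_codon or ""]
            )


def write_fasta(name: str, sequence: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")


def validate_circle(g: AnnotatedMitogenome) -> None:
    """Assert the circle closes: feature lengths plus spacers = genome length.

    Overlaps subtract, spacers add; evaluated around the full circle.  Only
    meaningful for annotations without nested features.
    """
    rep = intergenic_spacers(g)
    total = sum(feature_length(f, g.length) for f in g.features)
    total += sum(b[2] for b in rep.boundaries)
    total += rep.terminal_igs or 0
    first = g.features[0]
    total += first.start - 1  # leading gap before the first feature
    if total != g.genome_length:
        raise AnnotationError(
            f"circle does not close: features+spacers = {total}, "
            f"genome = {g.genome_length}"
        )


# ---------------------------------------------------------------------------
# Bundled published annotations for the two Phthorimaea mitogenomes
# ---------------------------------------------------------------------------

_SPECIES_FILES = {
    "P_absoluta": "phthorimaea_absoluta_mitogenome.tsv",
    "P_operculella": "phthorimaea_operculella_mitogenome.tsv",
}


def load_reference_annotation(species: str) -> tuple[AnnotatedMitogenome, IntergenicReport]:
    """Published mitogenome annotation of one of the two Phthorimaea species.

    ``species`` is ``"P_absoluta"`` (PA-KE, 15,295 bp) or ``"P_operculella"``
    (PO-KE, 15,269 bp); sequences are deposited under BioProject PRJNA902348.
    The bundled tables carry coordinates, strands and codons; the genome
    length is reconstructed from the last feature and the printed terminal
    spacer, so no sequence download is needed for the feature arithmetic.
    """
    from importlib.resources import as_file, files

    if species not in _SPECIES_FILES:
        raise KeyError(f"unknown species {species!r}; options: {list(_SPECIES_FILES)}")
    res = files("mitoniche.data") / _SPECIES_FILES[species]
    with as_file(res) as p:
        feats, meta = read_annotation_table(p)
    terminal = int(meta["terminal_igs"])
    genome = AnnotatedMitogenome(
        organism=meta.get("organism", species), features=feats
    )
    report = intergenic_spacers(genome, terminal_igs=terminal)
    genome.length = reconstruct_genome_length(
        report, genome.features[-1], genome.features[0]
    )
    return genome, report
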