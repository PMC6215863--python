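"""Reading, writing and slicing of genomes, CDS features and operon loci.

Internal coordinates are 0-based half-open throughout; GenBank's 1-based
inclusive convention and the loci TSV dialect (1-based inclusive) are
converted at the I/O boundary.  Sequences are normalized to uppercase DNA
(``U`` becomes ``T``); ambiguity codes are retained in the sequence and
handled downstream (k-mer counting skips windows containing them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

GENE_LABELS = ("xmoC", "xmoA", "xmoB")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an (ambiguity-code aware) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str, *, origin: str = "sequence") -> str:
    """Uppercase, map U->T, and validate against the IUPAC DNA alphabet.

    Raises ``ValueError`` naming the first offending position.
    """
    seq = raw.upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in IUPAC_DNA:
            raise ValueError(
                f"{origin}: non-IUPAC DNA character {ch!r} at position {i}"
            )
    return seq


@dataclass
class CdsFeature:
    """A protein-coding feature; ``parts`` carries join() spans in order."""

    gene_id: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"
    phase: int = 0
    parts: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.gene_id}: invalid strand {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"feature {self.gene_id}: invalid phase {self.phase}")

    @property
    def spans(self) -> list[tuple[int, int]]:
        return self.parts if self.parts is not None else [(self.start, self.end)]

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.spans)


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    topology: Literal["linear", "circular"] = "linear"
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def validate_features(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.spans:
                if s < 0 or e > n:
                    raise ValueError(
                        f"feature {f.gene_id} span [{s},{e}) outside genome "
                        f"{self.id} of length {n}"
                    )


@dataclass
class OperonLocus:
    """An xmo operon: ordered (label, feature) pairs on one genome.

    ``order_tag`` reflects the gene-label order along the coding strand:
    ``CAB`` (the common arrangement), ``ABC`` (the pxm arrangement), or
    ``other``.
    """

    genome_id: str
    operon_id: str
    genes: list[tuple[str, CdsFeature]]

    def __post_init__(self) -> None:
        ivals = sorted((f.start, f.end) for _, f in self.genes)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError(
                    f"operon {self.operon_id}: overlapping gene intervals"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(f.start for _, f in self.genes),
            max(f.end for _, f in self.genes),
        )

    @property
    def order_tag(self) -> str:
        by_pos = sorted(self.genes, key=lambda lf: lf[1].start)
        strands = {f.strand for _, f in self.genes}
        if strands == {"-"}:
            by_pos = by_pos[::-1]
        letters = "".join(label[-1].upper() for label, _ in by_pos)
        return letters if letters in ("CAB", "ABC") else "other"


def read_fasta(path) -> list[GenomeRecord]:
    """Read a multi-record FASTA into normalized :class:`GenomeRecord` s.

    Record ids are the first whitespace-delimited header token.  Rejects
    empty files, duplicate ids, records without sequence, and non-IUPAC
    characters (with position).
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"FASTA record {rec.id!r} has no sequence")
        seq = normalize_sequence(str(rec.seq), origin=f"record {rec.id!r}")
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_genbank_cds(path) -> GenomeRecord:
    """Read one GenBank flat file; keep only CDS features.

    GenBank 1-based inclusive locations arrive from Biopython already as
    0-based half-open; complement() becomes strand ``-`` and join() spans
    are kept in order in ``parts``.
    """
    rec = SeqIO.read(str(path), "genbank")
    topology = rec.annotations.get("topology", "linear")
    genome = GenomeRecord(
        id=rec.id,
        sequence=normalize_sequence(str(rec.seq), origin=f"record {rec.id!r}"),
        topology="circular" if topology == "circular" else "linear",
    )
    n = len(genome.sequence)
    for i, feat in enumerate(rec.features):
        if feat.type != "CDS":
            continue
        gene_id = feat.qualifiers.get(
            "locus_tag", feat.qualifiers.get("gene", [f"cds_{i}"])
        )[0]
        loc = feat.location
        spans = [(int(p.start), int(p.end)) for p in loc.parts]
        start, end = min(s for s, _ in spans), max(e for _, e in spans)
        if start < 0 or end > n:
            raise ValueError(
                f"CDS {gene_id} location [{start},{end}) outside sequence of length {n}"
            )
        strand = "-" if loc.strand == -1 else "+"
        phase = int(feat.qualifiers.get("codon_start", ["1"])[0]) - 1
        genome.features.append(
            CdsFeature(
                gene_id=gene_id,
                start=start,
                end=end,
                strand=strand,
                phase=phase,
                parts=spans if len(spans) > 1 else None,
            )
        )
    return genome


def extract_region(
    genome: GenomeRecord, start: int, end: int, strand: str = "+"
) -> str:
    """Slice [start, end) from a genome; minus strand reverse-complements.

    On circular genomes ``end`` may exceed the length and wraps around the
    origin; linear genomes reject out-of-bounds intervals.
    """
    n = len(genome.sequence)
    if start < 0 or end <= start:
        raise ValueError(f"invalid interval [{start},{end})")
    if end > n:
        if genome.topology != "circular" or start >= n or end - start > n:
            raise ValueError(
                f"interval [{start},{end}) outside linear genome of length {n}"
            )
        seq = genome.sequence[start:] + genome.sequence[: end - n]
    else:
        seq = genome.sequence[start:end]
    return reverse_complement(seq) if strand == "-" else seq


def cds_sequence(genome: GenomeRecord, feature: CdsFeature) -> str:
    """Coding sequence of a feature: join() spans concatenated, then
    strand-resolved, then phase-trimmed."""
    seq = "".join(genome.sequence[s:e] for s, e in feature.spans)
    if feature.strand == "-":
        seq = reverse_complement(seq)
    return seq[feature.phase :]


def operon_sequence(
    genome: GenomeRecord,
    locus: OperonLocus,
    mode: Literal["spanning", "concatenated_cds"] = "spanning",
) -> str:
    """Resolve an operon locus to sequence.

    ``spanning`` returns the forward-strand slice min(start)..max(end) — the
    whole locus as one region, suitable for k-mer composition (which is
    strand symmetric downstream).  ``concatenated_cds`` joins the coding
    sequences in operon order, each strand-resolved, for codon-usage work.
    """
    if mode == "spanning":
        strands = {f.strand for _, f in locus.genes}
        if len(strands) > 1 and locus.order_tag == "other":
            raise ValueError(
                f"operon {locus.operon_id}: genes on both strands with no "
                "recognizable order; spanning extraction is ambiguous"
            )
        s, e = locus.span
        return extract_region(genome, s, e, "+")
    if mode == "concatenated_cds":
        return "".join(cds_sequence(genome, f) for _, f in locus.genes)
    raise ValueError(f"unknown extraction mode {mode!r}")


# --- loci TSV dialect: genome_id, operon_id, gene_label, start, end, strand
#     (start/end 1-based inclusive in the file) ---

LOCI_COLUMNS = ["genome_id", "operon_id", "gene_label", "start", "end", "strand"]


def read_loci_tsv(path) -> list[OperonLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "operon_id": str})
    missing = set(LOCI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"loci table missing columns: {sorted(missing)}")
    loci = []
    for (gid, oid), grp in df.groupby(["genome_id", "operon_id"], sort=True):
        genes = [
            (
                row.gene_label,
                CdsFeature(
                    gene_id=f"{oid}_{row.gene_label}",
                    start=int(row.start) - 1,
                    end=int(row.end),
                    strand=row.strand,
                ),
            )
            for row in grp.itertuples()
        ]
        loci.append(OperonLocus(genome_id=gid, operon_id=oid, genes=genes))
    return loci


# --- CDS TSV dialect (GenBank-lite): genome_id, gene_id, start, end, strand
#     (start/end 1-based inclusive in the file) ---

CDS_COLUMNS = ["genome_id", "gene_id", "start", "end", "strand"]


def read_cds_tsv(path) -> dict[str, list[CdsFeature]]:
    """CDS features per genome id from the flat TSV dialect."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "gene_id": str})
    missing = set(CDS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CDS table missing columns: {sorted(missing)}")
    out: dict[str, list[CdsFeature]] = {}
    for row in df.itertuples():
        out.setdefault(row.genome_id, []).append(
            CdsFeature(
                gene_id=row.gene_id,
                start=int(row.start) - 1,
                end=int(row.end),
                strand=row.strand,
            )
        )
    return out


def write_cds_tsv(genomes: Iterable[GenomeRecord], path) -> None:
    rows = [
        {
            "genome_id": g.id,
            "gene_id": f.gene_id,
            "start": f.start + 1,
            "end": f.end,
            "strand": f.strand,
        }
        for g in genomes
        for f in g.features
    ]
    pd.DataFrame(rows, columns=CDS_COLUMNS).to_csv(path, sep="\t", index=False)


def write_loci_tsv(loci: Sequence[OperonLocus], path) -> None:
    rows = []
    for locus in loci:
        for label, f in locus.genes:
            rows.append(
                {
                    "genome_id": locus.genome_id,
                    "operon_id": locus.operon_id,
                    "gene_label": label,
                    "start": f.start + 1,
                    "end": f.end,
                    "strand": f.strand,
                }
            )
    pd.DataFrame(rows, columns=LOCI_COLUMNS).to_csv(path, sep="\t", index=False)
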