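"""Transcriptome model: genome + gene structures, derived introns and anchors.

Coordinates are 0-based half-open internally; GFF3/GTF conversion (1-based
inclusive) happens only at the I/O boundary.  One transcript model per gene:
overlapping isoforms are out of scope, matching the metagene feature sets this
package is built for (budding-yeast style annotations where almost every
intron-containing gene has a single intron).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import gffutils
from Bio import SeqIO

log = logging.getLogger(__name__)

# Anchor kinds for metagene alignment.
TSS = "TSS"   # transcription start site
PA = "PA"     # poly(A) / 3' cleavage site
SS3 = "SS3"   # 3' splice site == first nucleotide of exon 2
ANCHOR_KINDS = (TSS, PA, SS3)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for unusable genome/annotation input."""


@dataclass(frozen=True)
class TranscriptModel:
    """A single transcript: strand-aware exon chain with derived introns.

    ``exons`` are genomic [start, end) intervals listed in transcription order
    (for minus-strand genes that is decreasing genomic coordinate).  ``tss``
    and ``pa_site`` are the genomic coordinates of the first and last
    transcribed base, so ``tss > pa_site`` on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    pa_site: int
    exons: tuple[tuple[int, int], ...]
    gene_type: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: no exons")
        for s, e in self.exons:
            if not (0 <= s < e):
                raise AnnotationError(f"{self.gene_id}: bad exon [{s},{e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise AnnotationError(
                    f"{self.gene_id}: overlapping exons [{s1},{e1}) and [{s2},{e2})"
                )
        ordered = genomic if self.strand == "+" else genomic[::-1]
        if tuple(ordered) != tuple(self.exons):
            raise AnnotationError(f"{self.gene_id}: exons not in transcription order")
        if self.strand == "+" and self.tss > self.pa_site:
            raise AnnotationError(f"{self.gene_id}: tss > pa_site on + strand")
        if self.strand == "-" and self.tss < self.pa_site:
            raise AnnotationError(f"{self.gene_id}: tss < pa_site on - strand")

    # ---- derived geometry -------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        """Genomic [start, end) from TSS to pA inclusive of both."""
        if self.strand == "+":
            return (self.tss, self.pa_site + 1)
        return (self.pa_site, self.tss + 1)

    @property
    def length(self) -> int:
        s, e = self.span
        return e - s

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic [start, end) gaps between consecutive exons, transcription order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((a[1], b[0]))
            else:
                out.append((b[1], a[0]))
        return tuple(out)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    def mature_length(self) -> int:
        return sum(self.exon_lengths())

    def to_transcript_coord(self, genomic: int) -> int:
        """Gene-body (pre-mRNA) coordinate of a genomic position: 0 at the TSS."""
        if self.strand == "+":
            return genomic - self.tss
        return self.tss - genomic

    def to_genomic(self, t: int) -> int:
        if self.strand == "+":
            return self.tss + t
        return self.tss - t


@dataclass
class GenomeAnnotation:
    """Chromosome sequences plus one TranscriptModel per gene."""

    chromosomes: dict[str, str]
    genes: list[TranscriptModel]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise AnnotationError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom not in self.chromosomes:
                raise AnnotationError(
                    f"gene {g.gene_id} refers to missing chromosome {g.chrom!r}"
                )
            s, e = g.span
            if e > len(self.chromosomes[g.chrom]):
                raise AnnotationError(
                    f"gene {g.gene_id} exceeds chromosome {g.chrom} bounds"
                )

    def gene(self, gene_id: str) -> TranscriptModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def intron_containing(self) -> list[TranscriptModel]:
        return [g for g in self.genes if g.n_introns > 0]

    def counts(self) -> dict[str, int]:
        """Feature counts for the loaded annotation (reported, never assumed)."""
        return {
            "n_genes": len(self.genes),
            "n_intron_containing": len(self.intron_containing()),
            "n_chromosomes": len(self.chromosomes),
        }


@dataclass(frozen=True)
class AnchorSet:
    """Per-gene anchor positions for metagene alignment."""

    anchor_kind: str
    anchors: tuple[tuple[str, str, int, str], ...]  # (gene_id, chrom, position, strand)

    def __len__(self) -> int:
        return len(self.anchors)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def exon2_length(model: TranscriptModel) -> int | None:
    """Length of the exon immediately downstream of the first intron.

    Intronless genes have no exon 2 and return None.  For multi-intron genes
    this is the exon after the *first* intron in transcript orientation.
    """
    if model.n_introns == 0:
        return None
    s, e = model.exons[1]
    return e - s


def exon2_interval(model: TranscriptModel) -> tuple[int, int] | None:
    if model.n_introns == 0:
        return None
    return model.exons[1]


def make_anchors(ann: GenomeAnnotation, kind: str) -> AnchorSet:
    """Anchor positions for TSS / pA / 3'SS metagene alignment.

    The 3'SS anchor is the first nucleotide of exon 2 in transcript
    orientation (genomic start for + genes, genomic end-1 for - genes) and
    exists only for intron-containing genes.
    """
    if kind not in ANCHOR_KINDS:
        raise ValueError(f"unknown anchor kind {kind!r}")
    anchors = []
    for g in ann.genes:
        if kind == TSS:
            anchors.append((g.gene_id, g.chrom, g.tss, g.strand))
        elif kind == PA:
            anchors.append((g.gene_id, g.chrom, g.pa_site, g.strand))
        else:
            iv = exon2_interval(g)
            if iv is None:
                continue
            pos = iv[0] if g.strand == "+" else iv[1] - 1
            anchors.append((g.gene_id, g.chrom, pos, g.strand))
    if kind == SS3 and not anchors:
        warnings.warn("no intron-containing genes: empty SS3 anchor set")
    return AnchorSet(anchor_kind=kind, anchors=tuple(anchors))


def select_genes(
    ann: GenomeAnnotation,
    include_types: Sequence[str] = ("protein_coding",),
    exclude_chroms: Sequence[str] = ("chrM", "Mito", "mito"),
) -> list[str]:
    """Gene-class blacklist: keep protein-coding genes off excluded chromosomes.

    Stands in for the exclusion of RNAPI/RNAPIII transcripts and the
    mitochondrial genome before crosslink-site selection.
    """
    return [
        g.gene_id
        for g in ann.genes
        if g.gene_type in include_types and g.chrom not in exclude_chroms
    ]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _attr_first(attrs, *keys) -> str | None:
    for k in keys:
        if k in attrs:
            v = attrs[k]
            return v[0] if isinstance(v, (list, tuple)) else v
    return None


def load_annotation(genome_file: str, annotation_file: str) -> GenomeAnnotation:
    """Load FASTA + GFF3/GTF into a GenomeAnnotation.

    Both GFF3 (ID/Parent) and GTF (gene_id/transcript_id) dialects are
    accepted.  Transcript boundaries come from mRNA/transcript records when
    present, otherwise from the gene record (with a warning).  Malformed gene
    models (e.g. overlapping exons) are rejected per record with a diagnostic
    rather than aborting the whole load.
    """
    chromosomes = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(genome_file, "fasta")
    }
    if not chromosomes:
        raise AnnotationError(f"no sequences in {genome_file}")

    db = gffutils.create_db(
        str(annotation_file),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    gene_feats: dict[str, gffutils.Feature] = {}
    tx_by_gene: dict[str, list] = {}
    exons_by_parent: dict[str, list] = {}
    for f in db.all_features():
        if f.featuretype == "gene":
            gid = _attr_first(f.attributes, "ID", "gene_id")
            if gid:
                gene_feats.setdefault(gid, f)
        elif f.featuretype in ("mRNA", "transcript"):
            gid = _attr_first(f.attributes, "Parent", "gene_id")
            if gid:
                tx_by_gene.setdefault(gid, []).append(f)
        elif f.featuretype == "exon":
            parent = _attr_first(f.attributes, "Parent", "transcript_id")
            if parent:
                exons_by_parent.setdefault(parent, []).append(f)

    if not gene_feats and not tx_by_gene:
        raise AnnotationError(f"empty annotation: no gene/transcript records in {annotation_file}")

    gene_ids = list(gene_feats) or sorted(tx_by_gene)
    genes: list[TranscriptModel] = []
    diagnostics: list[str] = []
    for gid in gene_ids:
        gfeat = gene_feats.get(gid)
        txs = tx_by_gene.get(gid, [])
        if txs:
            if len(txs) > 1:
                log.warning("gene %s has %d transcripts; using the first", gid, len(txs))
            tx = sorted(txs, key=lambda f: (_attr_first(f.attributes, "ID", "transcript_id") or ""))[0]
        else:
            tx = gfeat
            log.warning("gene %s has no mRNA/transcript record; using gene bounds", gid)
        tid = _attr_first(tx.attributes, "ID", "transcript_id") or gid
        exon_feats = exons_by_parent.get(tid) or exons_by_parent.get(gid) or []
        if exon_feats:
            ivs = sorted((f.start - 1, f.end) for f in exon_feats)
        else:
            ivs = [(tx.start - 1, tx.end)]
        strand = tx.strand if tx.strand in "+-" else "+"
        start0, end0 = min(s for s, _ in ivs), max(e for _, e in ivs)
        tss, pa = (start0, end0 - 1) if strand == "+" else (end0 - 1, start0)
        ordered = ivs if strand == "+" else ivs[::-1]
        gtype = _attr_first(tx.attributes, "gene_biotype", "biotype") or (
            _attr_first(gfeat.attributes, "gene_biotype", "biotype") if gfeat is not None else None
        ) or "protein_coding"
        chrom = tx.seqid
        if chrom not in chromosomes:
            raise AnnotationError(f"gene {gid} refers to missing chromosome {chrom!r}")
        try:
            genes.append(
                TranscriptModel(
                    gene_id=gid, chrom=chrom, strand=strand, tss=tss,
                    pa_site=pa, exons=tuple(ordered), gene_type=gtype,
                )
            )
        except AnnotationError as exc:
            diagnostics.append(str(exc))
    if diagnostics:
        for d in diagnostics:
            log.warning("rejected gene model: %s", d)
    if not genes:
        raise AnnotationError("no valid gene models after validation")
    ann = GenomeAnnotation(chromosomes=chromosomes, genes=genes)
    log.info("loaded annotation: %s", ann.counts())
    return ann


def write_fasta(chromosomes: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in chromosomes:
            fh.write(f">{name}\n")
            seq = chromosomes[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(ann: GenomeAnnotation, path: str) -> None:
    """Emit gene/mRNA/exon records, 1-based inclusive (inverse of load)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            s, e = g.span
            base = (g.chrom, "cracsplice", "%s", str(s + 1), str(e), ".", g.strand, ".")
            fh.write("\t".join(base) % "gene" + f"\tID={g.gene_id};gene_biotype={g.gene_type}\n")
            tid = g.gene_id + "_mRNA"
            fh.write("\t".join(base) % "mRNA" + f"\tID={tid};Parent={g.gene_id}\n")
            for i, (es, ee) in enumerate(sorted(g.exons), 1):
                fh.write(
                    f"{g.chrom}\tcracsplice\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                    f"ID={tid}_exon{i};Parent={tid}\n"
                )


def anchors_to_bed(anchors: AnchorSet, path: str) -> None:
    """BED6 export: one single-base interval per anchor."""
    rows = sorted(anchors.anchors, key=lambda a: (a[1], a[2], a[0]))
    with open(path, "w") as fh:
        for gene_id, chrom, pos, strand in rows:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{gene_id}:{anchors.anchor_kind}\t0\t{strand}\n")
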