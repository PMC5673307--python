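"""CRAC read preprocessing: trim, filter, deduplicate, align, call crosslinks.

The chain mirrors the standard CRAC workflow: 3' adapter trimming with a
suffix/prefix scan (1 mismatch, 4 nt minimum overlap), removal of reads
lacking the adapter, a low-complexity filter (> 80% of one nucleotide),
collapse of PCR duplicates on (insert sequence, in-line barcode), exact-match
alignment allowing one single-nucleotide deletion (the crosslink signature),
a post-alignment duplicate collapse keyed on the strand-aware 5' end, and
assembly of overlapping reads into clusters.

The built-in aligner is intended for synthetic genomes with unique 25-mers;
real-data alignments are imported from SAM/BAM instead (``import_sam``).
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pysam

from .annotation import GenomeAnnotation, revcomp
from .simulate import canonical_deletion_position

log = logging.getLogger(__name__)

SEED_K = 12  # aligner seed length; deletions are recoverable from either end


# ---------------------------------------------------------------------------
# Read-level filters
# ---------------------------------------------------------------------------

def trim_adapter(
    seq: str, adapter: str, min_overlap: int = 4, allowed_mismatches: int = 1
) -> tuple[str, bool]:
    """Remove the longest read suffix matching an adapter prefix.

    A suffix of length >= ``min_overlap`` may mismatch the adapter prefix in
    at most ``allowed_mismatches`` positions.  Returns the trimmed sequence
    and whether an adapter was found (reads without one are discarded by the
    pipeline, which keeps only inserts sequenced through the 3' adapter).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    max_len = min(len(seq), len(adapter))
    for n in range(max_len, min_overlap - 1, -1):
        mm = sum(1 for a, b in zip(seq[-n:], adapter[:n]) if a != b)
        if mm <= allowed_mismatches:
            return seq[:-n], True
    return seq, False


def filter_low_complexity(seq: str, max_mono_fraction: float = 0.8) -> bool:
    """True (keep) unless one nucleotide makes up strictly more than the cutoff."""
    if not seq:
        log.warning("empty sequence dropped by low-complexity filter")
        return False
    most = Counter(seq).most_common(1)[0][1]
    return most / len(seq) <= max_mono_fraction


# ---------------------------------------------------------------------------
# FASTQ-level duplicate collapse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollapsedRead:
    """A deduplicated insert: identical (sequence, barcode) reads merged."""

    read_id: str
    seq: str
    barcode: str
    multiplicity: int


def collapse_fastq_duplicates(
    reads: Iterable[tuple[str, str, str]]
) -> list[CollapsedRead]:
    """Collapse reads identical in (insert sequence, barcode).

    ``reads`` yields (read_id, insert_seq, barcode).  The first read id of
    each group is kept; multiplicity is the group size.  Order follows first
    occurrence, so the operation is deterministic and idempotent.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    order: list[tuple[str, str]] = []
    ids: dict[tuple[str, str], str] = {}
    for rid, seq, bc in reads:
        key = (seq, bc)
        if key not in groups:
            groups[key] = []
            ids[key] = rid
            order.append(key)
        groups[key].append(rid)
    return [
        CollapsedRead(read_id=ids[k], seq=k[0], barcode=k[1], multiplicity=len(groups[k]))
        for k in order
    ]


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedRead:
    """A mapped read: ordered non-overlapping blocks plus deletion positions."""

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    deletion_positions: tuple[int, ...] = ()
    barcode: str = ""
    multiplicity: int = 1

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def five_prime_end(self) -> int:
        """Strand-aware 5' terminus: leftmost base for +, rightmost for -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)


class GenomeIndex:
    """Seed index over the forward genome for exact/1-deletion placement."""

    def __init__(self, chromosomes: dict[str, str], k: int = SEED_K):
        self.chromosomes = chromosomes
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom in sorted(chromosomes):
            seq = chromosomes[chrom]
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].append((chrom, i))

    def _forward_placements(self, q: str):
        """Exact and single-deletion placements of q on the forward strand."""
        k, L = self.k, len(q)
        exact: set[tuple[str, int]] = set()
        dele: dict[tuple[str, int], int] = {}
        span_starts: set[tuple[str, int, int]] = set()
        for chrom, p in self.index.get(q[:k], ()):  # seed anchored at read 5'
            span_starts.add((chrom, p, 0))
        for chrom, p in self.index.get(q[-k:], ()):  # seed anchored at read 3'
            span_starts.add((chrom, p + k - L, 1))      # exact candidate
            span_starts.add((chrom, p + k - L - 1, 2))  # deletion candidate
        for chrom, s, kind in span_starts:
            seq = self.chromosomes[chrom]
            if s < 0:
                continue
            if kind in (0, 1) and s + L <= len(seq) and seq[s : s + L] == q:
                exact.add((chrom, s))
            if kind in (0, 2):
                d = self._deletion_check(seq, s, q)
                if d is not None:
                    dele[(chrom, s)] = canonical_deletion_position(seq, d)
        return exact, dele

    @staticmethod
    def _deletion_check(seq: str, s: int, q: str) -> int | None:
        """Genomic deletion position if q matches seq[s:s+len(q)+1] minus one base."""
        L = len(q)
        if s < 0 or s + L + 1 > len(seq):
            return None
        i = 0
        while i < L and seq[s + i] == q[i]:
            i += 1
        if i == L:
            return None  # exact match; a deletion would fall outside the read
        if seq[s + i + 1 : s + L + 1] == q[i:]:
            return s + i
        return None

    def find_placements(self, q: str):
        """All candidate placements of q (both strands), exact preferred."""
        placements = []
        for strand, query in (("+", q), ("-", revcomp(q))):
            exact, dele = self._forward_placements(query)
            for chrom, s in sorted(exact):
                placements.append((chrom, strand, ((s, s + len(q)),), ()))
            for (chrom, s), d in sorted(dele.items()):
                if d <= s:
                    continue  # equivalent to an exact match starting one base right
                blocks = ((s, d), (d + 1, s + len(q) + 1))
                blocks = tuple(b for b in blocks if b[1] > b[0])
                placements.append((chrom, strand, blocks, (d,)))
        exacts = [p for p in placements if not p[3]]
        if exacts:
            return exacts
        # distinct spans that differ only by deletion position within one
        # homopolymer run have already been canonicalised; dedupe on span
        seen = {}
        for chrom, strand, blocks, dels in placements:
            key = (chrom, strand, blocks[0][0], blocks[-1][1], dels)
            seen.setdefault(key, (chrom, strand, blocks, dels))
        return list(seen.values())


def align_reads(
    reads: Sequence[CollapsedRead],
    genome: GenomeAnnotation | dict[str, str],
    max_deletions: int = 1,
) -> tuple[list[AlignedRead], dict[str, int]]:
    """Place each read at its unique exact match allowing <= 1 deletion.

    Reads with zero or multiple candidate placements are dropped and counted.
    ``max_deletions`` of 0 disables the deletion search.
    """
    chroms = genome.chromosomes if isinstance(genome, GenomeAnnotation) else genome
    index = GenomeIndex(chroms)
    aligned: list[AlignedRead] = []
    stats = {"n_unaligned": 0, "n_ambiguous": 0, "reads_unaligned": 0, "reads_ambiguous": 0}
    for read in reads:
        cands = index.find_placements(read.seq)
        if max_deletions == 0:
            cands = [c for c in cands if not c[3]]
        if len(cands) == 1:
            chrom, strand, blocks, dels = cands[0]
            aligned.append(
                AlignedRead(
                    read_id=read.read_id, chrom=chrom, strand=strand,
                    blocks=blocks, deletion_positions=dels,
                    barcode=read.barcode, multiplicity=read.multiplicity,
                )
            )
        elif not cands:
            stats["n_unaligned"] += 1
            stats["reads_unaligned"] += read.multiplicity
        else:
            stats["n_ambiguous"] += 1
            stats["reads_ambiguous"] += read.multiplicity
    if stats["n_ambiguous"]:
        log.warning(
            "%d reads dropped as multimapping (repeated sequence in genome)",
            stats["n_ambiguous"],
        )
    return aligned, stats


def collapse_aligned_duplicates(reads: Sequence[AlignedRead]) -> list[AlignedRead]:
    """Collapse reads sharing (chrom, strand, 5' end, barcode).

    Catches PCR duplicates that escaped sequence-level collapse through
    sequencing errors or differential 3' trimming: the longest representative
    is kept and multiplicities are summed.  Idempotent.
    """
    groups: dict[tuple, list[AlignedRead]] = {}
    order = []
    for r in reads:
        key = (r.chrom, r.strand, r.five_prime_end, r.barcode)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)
    out = []
    for key in order:
        members = groups[key]
        rep = max(members, key=lambda r: (r.aligned_length, r.read_id))
        out.append(replace(rep, multiplicity=sum(m.multiplicity for m in members)))
    return out


# ---------------------------------------------------------------------------
# Crosslink sites and clusters
# ---------------------------------------------------------------------------

@dataclass
class CrosslinkSiteSet:
    """Deletion-supported crosslink sites: (chrom, strand, position) -> count."""

    sites: dict[tuple[str, str, int], int]

    def __len__(self) -> int:
        return len(self.sites)

    def total(self) -> int:
        return sum(self.sites.values())

    def as_multiset(self) -> Counter:
        c = Counter()
        for key, n in self.sites.items():
            c[key] = n
        return c


def call_crosslink_sites(
    reads: Sequence[AlignedRead],
    ann: GenomeAnnotation | None = None,
    restrict_to: Iterable[str] | None = None,
) -> CrosslinkSiteSet:
    """Crosslink sites from single-deletion reads.

    Only reads with exactly one deletion contribute (two or more deletions
    are too ambiguous to pinpoint the crosslinked base); the site is the
    deleted genomic base and the count is the number of deduplicated reads
    supporting it.  With ``restrict_to``, sites outside the named genes'
    spans (same strand) are excluded.
    """
    spans = None
    if restrict_to is not None:
        if ann is None:
            raise ValueError("restrict_to requires the annotation")
        wanted = set(restrict_to)
        spans = defaultdict(list)
        for g in ann.genes:
            if g.gene_id in wanted:
                s, e = g.span
                spans[(g.chrom, g.strand)].append((s, e))
        for key in spans:
            spans[key].sort()
    sites: dict[tuple[str, str, int], int] = {}
    for r in reads:
        if len(r.deletion_positions) != 1:
            continue
        pos = r.deletion_positions[0]
        if spans is not None:
            ivs = spans.get((r.chrom, r.strand), [])
            i = bisect_right([s for s, _ in ivs], pos) - 1
            if i < 0 or not (ivs[i][0] <= pos < ivs[i][1]):
                continue
        key = (r.chrom, r.strand, pos)
        sites[key] = sites.get(key, 0) + 1
    return CrosslinkSiteSet(sites=sites)


@dataclass(frozen=True)
class Cluster:
    chrom: str
    strand: str
    start: int
    end: int
    seq: str
    n_reads: int


@dataclass
class ClusterSet:
    clusters: tuple[Cluster, ...]

    def __len__(self) -> int:
        return len(self.clusters)

    def sequences(self) -> list[str]:
        return [c.seq for c in self.clusters]


def assemble_clusters(
    reads: Sequence[AlignedRead], genome: GenomeAnnotation | dict[str, str]
) -> ClusterSet:
    """Merge overlapping same-strand reads into single cluster sequences.

    The cluster sequence is the genome sequence of the merged span in
    transcript orientation (reverse-complemented for minus-strand clusters).
    The result is independent of input read order.
    """
    chroms = genome.chromosomes if isinstance(genome, GenomeAnnotation) else genome
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for r in reads:
        by_key[(r.chrom, r.strand)].append((r.start, r.end))
    clusters = []
    for (chrom, strand) in sorted(by_key):
        spans = sorted(by_key[(chrom, strand)])
        cur_s, cur_e, n = spans[0][0], spans[0][1], 1
        merged = []
        for s, e in spans[1:]:
            if s < cur_e:  # strict overlap merges; abutting reads do not
                cur_e = max(cur_e, e)
                n += 1
            else:
                merged.append((cur_s, cur_e, n))
                cur_s, cur_e, n = s, e, 1
        merged.append((cur_s, cur_e, n))
        for s, e, n in merged:
            piece = chroms[chrom][s:e]
            clusters.append(
                Cluster(
                    chrom=chrom, strand=strand, start=s, end=e,
                    seq=piece if strand == "+" else revcomp(piece), n_reads=n,
                )
            )
    return ClusterSet(clusters=tuple(clusters))


# ---------------------------------------------------------------------------
# Pipeline and I/O
# ---------------------------------------------------------------------------

def split_barcode(seq: str, barcode_length: int) -> tuple[str, str]:
    return seq[:barcode_length], seq[barcode_length:]


def preprocess_reads(
    raw_reads: Sequence[tuple[str, str]],
    genome: GenomeAnnotation | dict[str, str],
    adapter: str,
    barcode_length: int = 6,
    min_length: int = 18,
    max_mono_fraction: float = 0.8,
    min_overlap: int = 4,
    allowed_mismatches: int = 1,
    collapse_aligned: bool = True,
) -> tuple[list[AlignedRead], dict[str, int]]:
    """Full preprocessing chain with a read-conservation report.

    reads_in == kept + sum of per-filter drop counts (in raw-read units).
    """
    report = {
        "reads_in": len(raw_reads),
        "no_adapter": 0,
        "too_short": 0,
        "low_complexity": 0,
    }
    survivors: list[tuple[str, str, str]] = []
    for rid, seq in raw_reads:
        trimmed, found = trim_adapter(seq, adapter, min_overlap, allowed_mismatches)
        if not found:
            report["no_adapter"] += 1
            continue
        barcode, insert = split_barcode(trimmed, barcode_length)
        if len(insert) < min_length:
            report["too_short"] += 1
            continue
        if not filter_low_complexity(insert, max_mono_fraction):
            report["low_complexity"] += 1
            continue
        survivors.append((rid, insert, barcode))
    collapsed = collapse_fastq_duplicates(survivors)
    report["molecules_after_dedup"] = len(collapsed)
    aligned, astats = align_reads(collapsed, genome)
    report["unaligned"] = astats["reads_unaligned"]
    report["ambiguous"] = astats["reads_ambiguous"]
    if collapse_aligned:
        aligned = collapse_aligned_duplicates(aligned)
    report["aligned_records"] = len(aligned)
    report["reads_kept"] = sum(r.multiplicity for r in aligned)
    report["conserved"] = report["reads_in"] == (
        report["no_adapter"]
        + report["too_short"]
        + report["low_complexity"]
        + report["unaligned"]
        + report["ambiguous"]
        + report["reads_kept"]
    )
    return aligned, report


def import_sam(path: str) -> list[AlignedRead]:
    """Import externally produced alignments (SAM/BAM) as AlignedReads.

    Blocks come from M/=/X cigar operations; 1 nt deletions are recorded as
    crosslink-candidate deletion positions; longer D and N operations split
    blocks.  The barcode is taken from the BC tag when present.
    """
    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            blocks: list[tuple[int, int]] = []
            dels: list[int] = []
            pos = read.reference_start
            cur_start = pos
            for op, length in read.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    pos += length
                elif op == 2:  # D
                    if length == 1:
                        dels.append(pos)
                    blocks.append((cur_start, pos))
                    pos += length
                    cur_start = pos
                elif op == 3:  # N
                    blocks.append((cur_start, pos))
                    pos += length
                    cur_start = pos
                # I, S, H consume no reference within a block
            if pos > cur_start:
                blocks.append((cur_start, pos))
            blocks = [b for b in blocks if b[1] > b[0]]
            if not blocks:
                continue
            barcode = read.get_tag("BC") if read.has_tag("BC") else ""
            out.append(
                AlignedRead(
                    read_id=read.query_name,
                    chrom=read.reference_name,
                    strand="-" if read.is_reverse else "+",
                    blocks=tuple(blocks),
                    deletion_positions=tuple(dels),
                    barcode=barcode,
                )
            )
    return out


def aligned_to_tsv(reads: Sequence[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstrand\tblocks\tdeletions\tbarcode\tmultiplicity\n")
        for r in reads:
            blocks = ",".join(f"{s}-{e}" for s, e in r.blocks)
            dels = ",".join(str(d) for d in r.deletion_positions)
            fh.write(
                f"{r.read_id}\t{r.chrom}\t{r.strand}\t{blocks}\t{dels}\t"
                f"{r.barcode}\t{r.multiplicity}\n"
            )


def aligned_from_tsv(path: str) -> list[AlignedRead]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, chrom, strand, blocks, dels, bc, mult = line.rstrip("\n").split("\t")
            out.append(
                AlignedRead(
                    read_id=rid,
                    chrom=chrom,
                    strand=strand,
                    blocks=tuple(
                        tuple(int(x) for x in b.split("-")) for b in blocks.split(",")
                    ),
                    deletion_positions=tuple(
                        int(d) for d in dels.split(",") if d
                    ),
                    barcode=bc,
                    multiplicity=int(mult),
                )
            )
    return out


def crosslinks_to_bed(sites: CrosslinkSiteSet, path: str) -> None:
    """BED6 export, score = supporting read count."""
    with open(path, "w") as fh:
        for (chrom, strand, pos), n in sorted(sites.sites.items()):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\txl\t{n}\t{strand}\n")


def clusters_to_bed(clusters: ClusterSet, path: str) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters.clusters):
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\tcluster{i}\t{c.n_reads}\t{c.strand}\n")
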