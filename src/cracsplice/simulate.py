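"""Synthetic CRAC / mCRAC / RNA-seq read generator with ground truth.

The generator emulates the statistical structure the downstream analyses
assume:

* a random genome carrying non-overlapping single- or two-exon genes;
* RNAPII-style occupancy with Gaussian pause bumps anchored at the pA site
  and the 5' end of exon 2, and depletion over the promoter-proximal region;
* CRAC reads with in-line random barcodes, PCR duplicate lineages, 3'
  adapters, low-complexity contaminants and single-nucleotide crosslink
  deletions at per-gene hotspot positions;
* a short motif planted into the genome at crosslink hotspots at a
  configurable rate (background occurrences scrubbed so the planted rate is
  a clean binomial);
* poly(A)+ / ribominus RNA-seq reads drawn from mixtures of spliced and
  unspliced molecules with genotype-dependent splicing efficiency.

Every read carries exactly one truth record so downstream stages can be
checked by oracle equivalence.  Fixing the seed fixes every output byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    PA,
    SS3,
    TSS,
    GenomeAnnotation,
    TranscriptModel,
    revcomp,
)

BASES = np.array(list("ACGT"))

# margin (nt) kept between a crosslink deletion and either end of the insert,
# so the deleted base is never ambiguous with a shifted exact match
DELETION_MARGIN = 10


def substream(seed: int, *labels) -> np.random.Generator:
    """Named, reproducible RNG substream derived from one top-level seed."""
    key = tuple(zlib.crc32(str(lab).encode()) % (2**31) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=key))


@dataclass(frozen=True)
class PauseComponent:
    """A Gaussian occupancy bump anchored at TSS/PA/SS3 plus an offset."""

    anchor_kind: str
    offset: int
    amplitude: float
    width: float


@dataclass
class SimulationConfig:
    """All knobs for the generator; defaults are the package's study conditions."""

    seed: int = 0
    n_genes: int = 20
    fraction_intron_containing: float = 0.5
    intergenic_gap: int = 300
    exon1_length_range: tuple[int, int] = (300, 1500)
    exon2_length_range: tuple[int, int] = (100, 1200)
    intron_length_range: tuple[int, int] = (80, 400)
    read_length: int = 50
    insert_length_range: tuple[int, int] = (24, 40)
    n_reads: int = 50_000
    splicing_efficiency: dict = field(default_factory=lambda: {"wt": 0.9, "mut": 0.7})
    pause_components: tuple[PauseComponent, ...] = (
        PauseComponent(PA, -200, 2.0, 30.0),
        PauseComponent(SS3, 20, 2.0, 30.0),
    )
    tss_depletion: tuple[int, float] = (150, 0.8)  # (width nt, depth)
    ub_amplification: float = 3.0  # bump amplitude multiplier for ub_pol
    crosslink_deletion_rate: float = 0.2
    hotspots_per_gene: int = 8
    pcr_duplicate_mean: float = 2.5
    barcode_length: int = 6
    adapter_sequence: str = "AGATCGGAAGAGC"
    low_complexity_rate: float = 0.01
    motif: str | None = "TTTG"
    motif_plant_rate: float = 0.7
    scrub_motif_background: bool = True
    nascent_fraction: float = 0.3  # ribominus share of 3'-incomplete molecules
    substitution_rate: float = 0.0
    min_overhang: int = 5
    quality_char: str = "I"

    def validate(self) -> None:
        for name in (
            "fraction_intron_containing",
            "crosslink_deletion_rate",
            "low_complexity_rate",
            "motif_plant_rate",
            "nascent_fraction",
            "substitution_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        for s in self.splicing_efficiency.values():
            if not 0.0 <= s <= 1.0:
                raise ValueError("splicing efficiency outside [0,1]")
        for pc in self.pause_components:
            if pc.width <= 0 or pc.amplitude < 0:
                raise ValueError("pause component needs width>0, amplitude>=0")
        if self.read_length < 2 * self.min_overhang:
            raise ValueError("read_length must be >= 2*min_overhang")
        if self.pcr_duplicate_mean < 1:
            raise ValueError("pcr_duplicate_mean must be >= 1")
        lo, hi = self.insert_length_range
        if lo < 2 * DELETION_MARGIN + 2:
            raise ValueError(
                f"insert_length_range min must be >= {2 * DELETION_MARGIN + 2}"
            )
        if hi + self.barcode_length + 4 > self.read_length:
            raise ValueError("inserts too long for the 3' adapter to be sequenced")

    def motif_dna(self) -> str | None:
        return self.motif.upper().replace("U", "T") if self.motif else None


def canonical_deletion_position(chrom_seq: str, pos: int) -> int:
    """Leftmost genomic base of the homopolymer run containing ``pos``.

    Deleting any base of a run yields the same read, so both the simulator
    truth and the aligner report the run's leftmost base.
    """
    c = chrom_seq[pos]
    i = pos
    while i > 0 and chrom_seq[i - 1] == c:
        i -= 1
    return i


def _run_length_at(seq: str, pos: int) -> int:
    c = seq[pos]
    i = pos
    while i > 0 and seq[i - 1] == c:
        i -= 1
    j = pos
    while j + 1 < len(seq) and seq[j + 1] == c:
        j += 1
    return j - i + 1


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, n: int) -> list[str]:
    return list(BASES[rng.integers(0, 4, size=n)])


def _scrub_motif(seq: list[str], motif: str, protected: list[tuple[int, int]],
                 rng: np.random.Generator) -> None:
    """Remove chance occurrences of the motif (both orientations) in place."""
    patterns = {motif, revcomp(motif)}
    for _ in range(200):
        text = "".join(seq)
        hits = []
        for pat in sorted(patterns):
            start = 0
            while True:
                i = text.find(pat, start)
                if i < 0:
                    break
                if not any(p0 < i + len(pat) and i < p1 for p0, p1 in protected):
                    hits.append(i)
                start = i + 1
        if not hits:
            return
        for i in sorted(set(hits)):
            mid = i + len(motif) // 2
            old = seq[mid]
            choices = [b for b in "ACGT" if b != old]
            seq[mid] = choices[rng.integers(0, 3)]
    raise RuntimeError("motif scrub did not converge")


def simulate_genome(cfg: SimulationConfig) -> tuple[GenomeAnnotation, pd.DataFrame]:
    """Random genome + gene models + per-gene truth (geometry and hotspots).

    The per-gene truth table records each gene's structure and its crosslink
    hotspot positions with their motif-planted flags.
    """
    cfg.validate()
    for attempt in range(5):
        rng = substream(cfg.seed, "genome", attempt)
        ann, truth = _simulate_genome_once(cfg, rng)
        if _kmers_unique(ann, k=25):
            return ann, truth
    raise RuntimeError("could not generate a genome with unique 25-mers")


def _simulate_genome_once(cfg, rng):
    n_ic = int(round(cfg.n_genes * cfg.fraction_intron_containing))
    ic_flags = np.zeros(cfg.n_genes, dtype=bool)
    ic_flags[rng.permutation(cfg.n_genes)[:n_ic]] = True

    structures = []
    for i in range(cfg.n_genes):
        e1 = int(rng.integers(cfg.exon1_length_range[0], cfg.exon1_length_range[1] + 1))
        if ic_flags[i]:
            ilen = int(rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1))
            e2 = int(rng.integers(cfg.exon2_length_range[0], cfg.exon2_length_range[1] + 1))
            structures.append((e1, ilen, e2))
        else:
            structures.append((e1, 0, 0))
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(cfg.n_genes)]

    total = cfg.intergenic_gap
    gene_starts = []
    for (e1, ilen, e2) in structures:
        gene_starts.append(total)
        total += e1 + ilen + e2 + cfg.intergenic_gap
    seq = _random_sequence(rng, total)

    motif = cfg.motif_dna()
    if motif and cfg.scrub_motif_background:
        _scrub_motif(seq, motif, [], rng)

    # identifiability: an intron boundary base equal to its exon partner makes
    # 1 nt junction overhangs sequence-identical between the spliced and
    # unspliced molecule forms; force the intron-side bases to differ
    def _fix_intron_boundaries(protected: list[tuple[int, int]]) -> None:
        for (e1, ilen, e2), strand, gstart in zip(structures, strands, gene_starts):
            if not ilen:
                continue
            is_ = gstart + (e1 if strand == "+" else e2)
            ie = is_ + ilen
            for ipos, partner in ((is_, ie), (ie - 1, is_ - 1)):
                if seq[ipos] != seq[partner]:
                    continue
                if any(p0 <= ipos < p1 for p0, p1 in protected):
                    continue
                for alt in "ACGT":
                    if alt == seq[partner] or alt == seq[ipos]:
                        continue
                    if motif and _would_create_motif(seq, ipos, alt, motif):
                        continue
                    seq[ipos] = alt
                    break

    _fix_intron_boundaries([])

    insert_max = cfg.insert_length_range[1]
    margin = insert_max + 2
    min_sep = 2 * insert_max + 20

    genes: list[TranscriptModel] = []
    rows = []
    protected: list[tuple[int, int]] = []
    for i, ((e1, ilen, e2), strand, gstart) in enumerate(
        zip(structures, strands, gene_starts)
    ):
        L = e1 + ilen + e2
        gend = gstart + L
        if strand == "+":
            tss, pa = gstart, gend - 1
            exons = ((gstart, gstart + e1), (gend - e2, gend)) if ilen else ((gstart, gend),)
        else:
            tss, pa = gend - 1, gstart
            exons = ((gend - e1, gend), (gstart, gstart + e2)) if ilen else ((gstart, gend),)
        model = TranscriptModel(
            gene_id=f"gene{i:04d}", chrom="chrS", strand=strand,
            tss=tss, pa_site=pa, exons=exons,
        )
        genes.append(model)

        # hotspots: transcript coords with spacing, away from gene ends, in
        # short homopolymer context so the deletion cannot touch a read edge
        hotspots: list[tuple[int, bool]] = []
        n_want = cfg.hotspots_per_gene if L > 2 * margin + min_sep else max(
            1, (L - 2 * margin) // min_sep
        )
        boundary_bases = set()
        if ilen:
            is_ = gstart + (e1 if strand == "+" else e2)
            boundary_bases = {is_, is_ + ilen - 1}
        attempts = 0
        while len(hotspots) < n_want and attempts < 400:
            attempts += 1
            t = int(rng.integers(margin, L - margin))
            if any(abs(t - h) < min_sep for h, _ in hotspots):
                continue
            g = model.to_genomic(t)
            if any(abs(g - b) <= 8 for b in boundary_bases):
                continue
            planted = bool(motif) and (rng.random() < cfg.motif_plant_rate)
            if motif:
                if strand == "+":
                    lo, pat = g, motif
                else:
                    lo, pat = g - len(motif) + 1, revcomp(motif)
                local = seq[max(0, lo - 8) : lo] + list(pat) + seq[lo + len(pat) : lo + len(pat) + 8]
                if _run_length_at("".join(local), min(8, lo) ) > 6:
                    continue
                if planted:
                    for k, b in enumerate(pat):
                        seq[lo + k] = b
                    protected.append((lo, lo + len(pat)))
            if _run_length_at("".join(seq[max(0, g - 8) : g + 9]), min(8, g)) > 6:
                continue
            hotspots.append((t, planted))
        hotspots.sort()
        rows.append(
            {
                "gene_id": model.gene_id,
                "chrom": model.chrom,
                "strand": strand,
                "tss": tss,
                "pa_site": pa,
                "length": L,
                "exon1_length": e1,
                "intron_length": ilen,
                "exon2_length": e2 if ilen else np.nan,
                "hotspots": ";".join(
                    f"{t}:{int(pl)}:{model.to_genomic(t)}" for t, pl in hotspots
                ),
            }
        )

    if motif and cfg.scrub_motif_background:
        _scrub_motif(seq, motif, protected, rng)
    _fix_intron_boundaries(protected)

    ann = GenomeAnnotation(chromosomes={"chrS": "".join(seq)}, genes=genes)
    return ann, pd.DataFrame(rows)


def _would_create_motif(seq: list[str], pos: int, alt: str, motif: str) -> bool:
    k = len(motif)
    lo = max(0, pos - k + 1)
    window = seq[lo : pos] + [alt] + seq[pos + 1 : pos + k]
    text = "".join(window)
    return motif in text or revcomp(motif) in text


def _kmers_unique(ann: GenomeAnnotation, k: int = 25) -> bool:
    seen: set[str] = set()
    for seq in ann.chromosomes.values():
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            rc = revcomp(km)
            if km in seen or rc in seen:
                return False
            seen.add(km)
    return True


def parse_hotspots(row) -> list[tuple[int, bool, int]]:
    """(transcript pos, planted?, genomic pos) triples from a gene-truth row."""
    if not row["hotspots"]:
        return []
    out = []
    for item in row["hotspots"].split(";"):
        t, pl, g = item.split(":")
        out.append((int(t), bool(int(pl)), int(g)))
    return out


# ---------------------------------------------------------------------------
# Occupancy model
# ---------------------------------------------------------------------------

def gene_occupancy(model: TranscriptModel, cfg: SimulationConfig,
                   sample_kind: str = "total_pol") -> np.ndarray:
    """True polymerase occupancy over the gene body (transcript coordinates).

    occupancy(x) = (1 - depletion(x)) * (1 + sum of Gaussian bumps), with the
    bump amplitudes multiplied by ``ub_amplification`` for the ub_pol sample.
    """
    L = model.length
    x = np.arange(L, dtype=float)
    width, depth = cfg.tss_depletion
    base = np.where(x < width, 1.0 - depth, 1.0)
    scale = cfg.ub_amplification if sample_kind == "ub_pol" else 1.0
    bumps = np.zeros(L)
    for pc in cfg.pause_components:
        if pc.anchor_kind == TSS:
            center = 0 + pc.offset
        elif pc.anchor_kind == PA:
            center = (L - 1) + pc.offset
        elif pc.anchor_kind == SS3:
            if model.n_introns == 0:
                continue
            e1 = model.exon_lengths()[0]
            ilen = model.introns and (
                abs(model.introns[0][1] - model.introns[0][0])
            )
            center = e1 + ilen + pc.offset
        else:
            raise ValueError(pc.anchor_kind)
        bumps += scale * pc.amplitude * np.exp(-((x - center) ** 2) / (2 * pc.width**2))
    return base * (1.0 + bumps)


# ---------------------------------------------------------------------------
# CRAC read simulation
# ---------------------------------------------------------------------------

SAMPLE_KINDS = ("protein_CRAC", "total_pol", "ub_pol")


def _oriented_insert(chrom: str, model: TranscriptModel, x0: int, ilen: int,
                     del_t: int | None) -> tuple[str, int]:
    """Insert sequence for transcript window [x0, x0+ilen), 5'->3'.

    With a crosslink the genomic span is one base longer and the base at
    transcript coordinate ``del_t`` is skipped.  Returns (sequence, canonical
    genomic deletion position or -1).
    """
    span = ilen + (1 if del_t is not None else 0)
    if model.strand == "+":
        lo = model.tss + x0
        hi = lo + span
        piece = chrom[lo:hi]
        if del_t is None:
            return piece, -1
        g = model.tss + del_t
        seq = chrom[lo:g] + chrom[g + 1 : hi]
    else:
        hi = model.tss - x0 + 1
        lo = hi - span
        if del_t is None:
            return revcomp(chrom[lo:hi]), -1
        g = model.tss - del_t
        seq = revcomp(chrom[lo:g] + chrom[g + 1 : hi])
    return seq, canonical_deletion_position(chrom, g)


def simulate_crac_reads(
    ann: GenomeAnnotation,
    cfg: SimulationConfig,
    sample_kind: str,
    gene_truth: pd.DataFrame,
    replicate: int = 0,
    n_reads: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """CRAC/mCRAC FASTQ records plus a per-read truth table.

    Non-crosslinked molecules start where the occupancy model puts the
    polymerase; crosslinked molecules are anchored at a hotspot, carry a
    single-nucleotide deletion there, and the read covers the hotspot with a
    margin on both sides.  Molecules are PCR-duplicated (shared barcode) and
    low-complexity junk is injected at the configured rate.
    """
    if sample_kind not in SAMPLE_KINDS:
        raise ValueError(f"unknown sample kind {sample_kind!r}")
    cfg.validate()
    rng = substream(cfg.seed, "crac", sample_kind, replicate)
    n_reads = n_reads if n_reads is not None else cfg.n_reads
    n_mol = max(1, int(round(n_reads / cfg.pcr_duplicate_mean)))
    imin, imax = cfg.insert_length_range

    hotspot_map = {
        row["gene_id"]: parse_hotspots(row) for _, row in gene_truth.iterrows()
    }
    occs = []
    for g in ann.genes:
        occ = gene_occupancy(g, cfg, sample_kind)[: g.length - imax - 2]
        occs.append(occ)
    weights = np.array([o.sum() for o in occs])
    per_gene = rng.multinomial(n_mol, weights / weights.sum())

    reads: list[tuple[str, str]] = []
    truth_rows = []
    mol_id = 0
    for g, occ, k in zip(ann.genes, occs, per_gene):
        if k == 0:
            continue
        chrom = ann.chromosomes[g.chrom]
        hotspots = hotspot_map.get(g.gene_id, [])
        p = occ / occ.sum()
        n_x = rng.binomial(k, cfg.crosslink_deletion_rate) if hotspots else 0
        starts_plain = rng.choice(len(occ), size=k - n_x, p=p)
        ilens = rng.integers(imin, imax + 1, size=k)
        hs_idx = rng.integers(0, len(hotspots), size=n_x) if n_x else []
        for j in range(k):
            ilen = int(ilens[j])
            if j < n_x:
                t_hot, planted, _ = hotspots[hs_idx[j]]
                u = int(rng.integers(DELETION_MARGIN, ilen - DELETION_MARGIN))
                x0 = t_hot - u
                insert, gdel = _oriented_insert(chrom, g, x0, ilen, t_hot)
            else:
                x0 = int(starts_plain[j - n_x])
                insert, gdel = _oriented_insert(chrom, g, x0, ilen, None)
            barcode = "".join(BASES[rng.integers(0, 4, cfg.barcode_length)])
            ndup = 1 + int(rng.poisson(cfg.pcr_duplicate_mean - 1.0))
            for d in range(ndup):
                ins = insert
                if cfg.substitution_rate > 0:
                    ins = _mutate(ins, cfg.substitution_rate, rng)
                body = barcode + ins
                room = cfg.read_length - len(body)
                if room > 0:
                    body += cfg.adapter_sequence[:room]
                rid = f"{sample_kind}_{mol_id:07d}_{d}"
                reads.append((rid, body))
                truth_rows.append(
                    {
                        "read_id": rid,
                        "gene_id": g.gene_id,
                        "strand": g.strand,
                        "lineage": mol_id,
                        "t_start": x0,
                        "insert_length": ilen,
                        "crosslink_pos": gdel,
                        "barcode": barcode,
                        "is_junk": False,
                    }
                )
            mol_id += 1

    n_junk = rng.binomial(len(reads), cfg.low_complexity_rate)
    for j in range(n_junk):
        base = str(BASES[rng.integers(0, 4)])
        chars = [
            base if rng.random() < 0.92 else str(BASES[rng.integers(0, 4)])
            for _ in range(cfg.read_length)
        ]
        rid = f"{sample_kind}_junk_{j:05d}"
        reads.append((rid, "".join(chars)))
        truth_rows.append(
            {
                "read_id": rid, "gene_id": None, "strand": None,
                "lineage": -1, "t_start": -1, "insert_length": -1,
                "crosslink_pos": -1, "barcode": None, "is_junk": True,
            }
        )
    return reads, pd.DataFrame(truth_rows)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alt = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alt[rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

def _mature_seq(chrom: str, model: TranscriptModel) -> str:
    parts = []
    for s, e in model.exons:
        piece = chrom[s:e]
        parts.append(piece if model.strand == "+" else revcomp(piece))
    return "".join(parts)


def _pre_seq(chrom: str, model: TranscriptModel) -> str:
    s, e = model.span
    piece = chrom[s:e]
    return piece if model.strand == "+" else revcomp(piece)


def _truth_label(model: TranscriptModel, spliced: bool, t: int, R: int, o: int):
    """Junction label + intron-overlap flag in molecule coordinates.

    Independent of the genomic-block classifier: works purely from the
    molecule class and the read's start within it.
    """
    if model.n_introns == 0:
        return "exonic", False
    e1 = model.exon_lengths()[0]
    ilen = model.length - model.mature_length()
    if spliced:
        c = e1
        if c - t >= o and (t + R) - c >= o:
            return "EE", False
        return "exonic", False
    a, b = e1, e1 + ilen
    if t <= a - o and t + R >= a + o:
        return "EI", True
    if t <= b - o and t + R >= b + o:
        return "IE", True
    ibases = max(0, min(t + R, b) - max(t, a))
    if ibases > R - ibases:
        return "intronic", ibases > 0
    return "exonic", ibases > 0


def simulate_rnaseq_reads(
    ann: GenomeAnnotation,
    cfg: SimulationConfig,
    genotype: str,
    library_kind: str = "polyA",
    replicate: int = 0,
    n_reads: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Poly(A)+ or ribominus RNA-seq reads with per-read truth labels.

    Each sampled molecule is spliced with the genotype's splicing efficiency.
    The poly(A)+ library draws only full-length molecules; ribominus
    additionally draws unspliced nascent molecules truncated at a uniform
    position between TSS and pA.  Reads are sampled uniformly along the
    molecule.
    """
    cfg.validate()
    if genotype not in cfg.splicing_efficiency:
        raise ValueError(f"genotype {genotype!r} has no splicing efficiency")
    if library_kind not in ("polyA", "ribominus"):
        raise ValueError(f"unknown library kind {library_kind!r}")
    rng = substream(cfg.seed, "rnaseq", genotype, library_kind, replicate)
    s_eff = cfg.splicing_efficiency[genotype]
    R = cfg.read_length
    o = cfg.min_overhang
    n = n_reads if n_reads is not None else cfg.n_reads

    pre = {g.gene_id: _pre_seq(ann.chromosomes[g.chrom], g) for g in ann.genes}
    mat = {g.gene_id: _mature_seq(ann.chromosomes[g.chrom], g) for g in ann.genes}

    gene_idx = rng.integers(0, len(ann.genes), size=n)
    u_splice = rng.random(n)
    u_nascent = rng.random(n) if library_kind == "ribominus" else np.ones(n)
    u_start = rng.random(n)
    u_trunc = rng.random(n)

    sample = f"{genotype}_{library_kind}_r{replicate}"
    reads = []
    rows = []
    for i in range(n):
        g = ann.genes[int(gene_idx[i])]
        nascent = u_nascent[i] < cfg.nascent_fraction
        if nascent:
            spliced = False
            mol = pre[g.gene_id]
            trunc = R + int(u_trunc[i] * (len(mol) - R + 1))
            mol = mol[:trunc]
        else:
            spliced = u_splice[i] < s_eff
            mol = mat[g.gene_id] if spliced else pre[g.gene_id]
        t = int(u_start[i] * (len(mol) - R + 1))
        label, has_i = _truth_label(g, spliced, t, R, o)
        rid = f"{sample}_{i:07d}"
        reads.append((rid, mol[t : t + R]))
        rows.append(
            {
                "read_id": rid,
                "sample": sample,
                "gene_id": g.gene_id,
                "mol_class": "nascent" if nascent else ("spliced" if spliced else "unspliced"),
                "t_start": t,
                "junction_label": label,
                "has_intronic": has_i,
            }
        )
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FASTQ / truth I/O
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[tuple[str, str]], path: str, quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((header[1:].strip(), seq))
    return out
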