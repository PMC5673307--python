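"""Anchored, strand-aware metagene profiles with replicate statistics.

Signal (read 5' ends, coverage, or crosslink sites) is mapped to offsets
relative to per-gene anchors (TSS, pA or 3'SS) in transcript orientation —
minus-strand genes are flipped — summed across genes and normalised to reads
per million mapped reads (RPM).  Modified-vs-total comparisons are expressed
as per-offset enrichment ratios of two RPM profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .annotation import AnchorSet, GenomeAnnotation, exon2_length, make_anchors, SS3
from .preprocess import AlignedRead

log = logging.getLogger(__name__)

SIGNALS = ("five_prime_ends", "coverage", "crosslink_sites")

# default windows (nt relative to anchor); configurable, recorded in outputs
DEFAULT_WINDOWS = {"TSS": (-100, 1000), "PA": (-1000, 200), "SS3": (-200, 600)}


@dataclass
class MetageneProfile:
    """Per-offset signal around a named anchor, summed over genes."""

    anchor_kind: str
    window: tuple[int, int]
    values: np.ndarray
    n_features: int
    normalization: str = "RPM"
    sd: np.ndarray | None = None
    n_replicates: int = 1
    signal: str = "five_prime_ends"

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + 1)

    def __post_init__(self) -> None:
        expect = self.window[1] - self.window[0] + 1
        if len(self.values) != expect:
            raise ValueError("values length does not match window")


@dataclass
class EnrichmentProfile:
    """Per-offset ratio of two RPM profiles (e.g. ubiquitinated vs total)."""

    anchor_kind: str
    window: tuple[int, int]
    values: np.ndarray
    pseudocount: float

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.window[0], self.window[1] + 1)


def _chrom_lengths(genome) -> dict[str, int]:
    if isinstance(genome, GenomeAnnotation):
        return {c: len(s) for c, s in genome.chromosomes.items()}
    first = next(iter(genome.values()), "")
    if isinstance(first, str):
        return {c: len(s) for c, s in genome.items()}
    return dict(genome)


def build_signal_arrays(
    reads: Sequence[AlignedRead],
    genome,
    signal: str = "five_prime_ends",
) -> dict[tuple[str, str], np.ndarray]:
    """Genome-wide per-strand signal arrays, PCR-multiplicity aware."""
    if signal not in SIGNALS:
        raise ValueError(f"unknown signal {signal!r}")
    lengths = _chrom_lengths(genome)
    arrays = {
        (c, strand): np.zeros(n) for c, n in lengths.items() for strand in "+-"
    }
    for r in reads:
        arr = arrays.get((r.chrom, r.strand))
        if arr is None:
            continue
        w = r.multiplicity
        if signal == "five_prime_ends":
            arr[r.five_prime_end] += w
        elif signal == "coverage":
            for s, e in r.blocks:
                arr[s:e] += w
        else:
            for d in r.deletion_positions:
                arr[d] += w
    return arrays


def metagene_profile(
    reads: Sequence[AlignedRead],
    anchors: AnchorSet,
    genome,
    window: tuple[int, int] | None = None,
    signal: str = "five_prime_ends",
    total_mapped: int | None = None,
    per_gene_mean: bool = False,
) -> MetageneProfile:
    """RPM-normalised signal around the anchors, transcript orientation.

    ``total_mapped`` defaults to the multiplicity-weighted number of mapped
    reads in ``reads`` (library-size normalisation over everything mapped,
    not only profiled genes).  ``per_gene_mean`` divides the summed profile
    by the number of anchors, equalising gene weights.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    if window is None:
        window = DEFAULT_WINDOWS[anchors.anchor_kind]
    omin, omax = window
    if omax < omin:
        raise ValueError("window max < min")
    if not reads:
        warnings.warn("empty read set: zero profile")
    arrays = build_signal_arrays(reads, genome, signal)
    width = omax - omin + 1
    acc = np.zeros(width)
    for gene_id, chrom, pos, strand in anchors.anchors:
        arr = arrays[(chrom, strand)]
        n = len(arr)
        if strand == "+":
            lo, hi = pos + omin, pos + omax + 1
            lo_c, hi_c = max(lo, 0), min(hi, n)
            if lo_c < hi_c:
                acc[lo_c - lo : hi_c - lo] += arr[lo_c:hi_c]
        else:
            lo, hi = pos - omax, pos - omin + 1
            lo_c, hi_c = max(lo, 0), min(hi, n)
            if lo_c < hi_c:
                seg = arr[lo_c:hi_c][::-1]
                acc[width - (hi_c - lo) : width - (lo_c - lo)] = (
                    acc[width - (hi_c - lo) : width - (lo_c - lo)] + seg
                )
    total = (
        total_mapped
        if total_mapped is not None
        else sum(r.multiplicity for r in reads)
    )
    values = acc / (total / 1e6) if total > 0 else acc
    if per_gene_mean:
        values = values / len(anchors)
    return MetageneProfile(
        anchor_kind=anchors.anchor_kind,
        window=window,
        values=values,
        n_features=len(anchors),
        normalization="RPM" + ("/gene" if per_gene_mean else ""),
        signal=signal,
    )


def average_replicates(profiles: Sequence[MetageneProfile]) -> MetageneProfile:
    """Pointwise mean and sample standard deviation across replicates.

    A single replicate yields sd == 0 with ``n_replicates`` recording that
    the spread is undefined rather than truly zero.
    """
    if not profiles:
        raise ValueError("no profiles")
    first = profiles[0]
    for p in profiles[1:]:
        if p.window != first.window or p.anchor_kind != first.anchor_kind:
            raise ValueError("profiles have mismatched anchor kind or window")
    stack = np.vstack([p.values for p in profiles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros_like(mean)
    return MetageneProfile(
        anchor_kind=first.anchor_kind,
        window=first.window,
        values=mean,
        sd=sd,
        n_features=first.n_features,
        normalization=first.normalization,
        n_replicates=len(profiles),
        signal=first.signal,
    )


def stratify_profiles(
    reads: Sequence[AlignedRead],
    ann: GenomeAnnotation,
    window: tuple[int, int] | None = None,
    threshold: int = 600,
    signal: str = "five_prime_ends",
    total_mapped: int | None = None,
) -> tuple[MetageneProfile, MetageneProfile]:
    """3'SS-anchored profiles for long- vs short-exon-2 genes.

    "Long" means exon 2 strictly longer than the threshold (default 600 nt);
    genes at exactly the threshold go to the short stratum.
    """
    full = make_anchors(ann, SS3)
    e2 = {g.gene_id: exon2_length(g) for g in ann.genes}
    long_a = tuple(a for a in full.anchors if e2[a[0]] and e2[a[0]] > threshold)
    short_a = tuple(a for a in full.anchors if e2[a[0]] and e2[a[0]] <= threshold)
    out = []
    for name, sel in (("long", long_a), ("short", short_a)):
        if not sel:
            warnings.warn(f"empty {name} exon-2 stratum: zero profile")
            w = window or DEFAULT_WINDOWS[SS3]
            out.append(
                MetageneProfile(
                    anchor_kind=SS3, window=w,
                    values=np.zeros(w[1] - w[0] + 1), n_features=0, signal=signal,
                )
            )
            continue
        out.append(
            metagene_profile(
                reads, AnchorSet(SS3, sel), ann, window=window,
                signal=signal, total_mapped=total_mapped,
            )
        )
    return out[0], out[1]


def relative_enrichment(
    numerator: MetageneProfile,
    denominator: MetageneProfile,
    pseudocount: float = 0.1,
) -> EnrichmentProfile:
    """(num + pc)/(den + pc) per offset; defined everywhere for pc > 0."""
    if numerator.window != denominator.window:
        raise ValueError("profiles have mismatched windows")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    values = (numerator.values + pseudocount) / (denominator.values + pseudocount)
    return EnrichmentProfile(
        anchor_kind=numerator.anchor_kind,
        window=numerator.window,
        values=values,
        pseudocount=pseudocount,
    )


def profile_peak(
    profile: MetageneProfile | EnrichmentProfile, smoothing_halfwidth: int = 5
) -> tuple[int | None, float | None]:
    """Offset and value of the maximum of the moving-average-smoothed profile.

    Ties go to the smallest offset.  All-zero profiles have no peak.
    """
    v = np.asarray(profile.values, dtype=float)
    if not np.any(v != 0):
        return None, None
    if smoothing_halfwidth > 0:
        w = 2 * smoothing_halfwidth + 1
        kernel = np.ones(w)
        # edge-corrected moving average: divide by the in-window count
        sm = np.convolve(v, kernel, mode="same") / np.convolve(
            np.ones_like(v), kernel, mode="same"
        )
    else:
        sm = v
    # ties in the smoothed profile break on the raw signal, then smallest offset
    cand = np.flatnonzero(sm >= sm.max() - 1e-12)
    i = int(cand[np.argmax(v[cand])])
    offs = profile.offsets
    return int(offs[i]), float(sm[i])


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def profile_to_tsv(profile: MetageneProfile, path: str) -> None:
    sd = profile.sd if profile.sd is not None else np.zeros_like(profile.values)
    with open(path, "w") as fh:
        fh.write(f"# anchor={profile.anchor_kind} window={profile.window} "
                 f"signal={profile.signal} normalization={profile.normalization} "
                 f"n_features={profile.n_features} n_replicates={profile.n_replicates}\n")
        fh.write("offset\tmean\tsd\n")
        for o, m, s in zip(profile.offsets, profile.values, sd):
            fh.write(f"{o}\t{m!r}\t{s!r}\n")


def signal_to_bedgraph(
    reads: Sequence[AlignedRead], genome, prefix: str,
    signal: str = "five_prime_ends",
) -> None:
    """One BEDGRAPH per strand of raw (unnormalised) genome-wide signal."""
    arrays = build_signal_arrays(reads, genome, signal)
    for strand, tag in (("+", "plus"), ("-", "minus")):
        with open(f"{prefix}.{tag}.bedgraph", "w") as fh:
            for (chrom, st), arr in sorted(arrays.items()):
                if st != strand:
                    continue
                nz = np.flatnonzero(arr)
                for i in nz:
                    fh.write(f"{chrom}\t{i}\t{i + 1}\t{arr[i]!r}\n")


def plot_profiles(profiles: Mapping[str, MetageneProfile], path: str) -> None:
    """Replicate-mean profiles with an sd shadow, one panel per anchor set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, p in profiles.items():
        ax.plot(p.offsets, p.values, label=label)
        if p.sd is not None:
            ax.fill_between(
                p.offsets, p.values - p.sd, p.values + p.sd, alpha=0.3, color="grey"
            )
    ax.set_xlabel("position relative to anchor (nt)")
    ax.set_ylabel(next(iter(profiles.values())).normalization)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
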