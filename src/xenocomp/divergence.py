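"""The region-versus-genome Kullback–Leibler statistic and the windowed
alien-region scan.

The core quantity is D_KL(region || genome) = Σ_i p_i ln(p_i / q_i) in nats,
where p is the region's compositional profile and q the whole genome's
(including the region itself — no leave-one-out).  Both profiles receive a
Laplace pseudocount (default 1 per category) before normalization, which
keeps the divergence finite when a short region misses categories the
genome has.  A bounded companion score, score01 = 1 − exp(−KL), maps the
divergence monotonically onto [0, 1): values near 0 mean the region matches
its genome's signature, values near 1 mean strongly foreign composition.

The scan slides a window (default 2500 bp) along the genome, computes the
per-k KL against the whole-genome profile for k = 2..8, and combines them
with geometrically decaying weights w_k ∝ 4^−(k−2) (higher orders are
noisier in windows of a few kb).  Calling turns window scores into merged
"alien" intervals via an exact 1-D 2-means split with an effect-size guard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .composition import CompositionProfile, count_kmers, encode_dna, kmer_profile
from .genome_io import GenomeRecord, OperonLocus, cds_sequence, operon_sequence

logger = logging.getLogger(__name__)


@dataclass
class DivergenceResult:
    region_id: str
    genome_id: str
    method: Literal["tetra", "codon", "window"]
    kl_nats: float
    score01: float


@dataclass
class WindowScore:
    start: int
    end: int
    combined_kl: float
    per_k: dict[int, float] = field(default_factory=dict)


@dataclass
class AlienRegionCall:
    start: int
    end: int
    peak_score: float
    threshold: float
    overlapping_operons: list[str] = field(default_factory=list)


def _smoothed_freqs(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    c = counts + pseudocount
    return c / c.sum()


def kl_nats_from_counts(
    region_counts: np.ndarray, genome_counts: np.ndarray, pseudocount: float = 1.0
) -> float:
    """KL in nats between pseudocount-smoothed count vectors."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    p = _smoothed_freqs(np.asarray(region_counts, dtype=float), pseudocount)
    q = _smoothed_freqs(np.asarray(genome_counts, dtype=float), pseudocount)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def score01_from_kl(kl_nats: float) -> float:
    """Monotone map of KL (nats) onto [0, 1): 1 − exp(−KL)."""
    return float(-np.expm1(-kl_nats))


def kl_divergence(
    region: CompositionProfile,
    genome: CompositionProfile,
    pseudocount: float = 1.0,
    method: Literal["tetra", "codon", "window"] = "tetra",
) -> DivergenceResult:
    """KL divergence of a region's profile relative to its genome's."""
    if not region.same_alphabet(genome):
        raise ValueError(
            f"alphabet mismatch: {region.alphabet_kind}(k={region.k}) vs "
            f"{genome.alphabet_kind}(k={genome.k})"
        )
    kl = kl_nats_from_counts(region.counts, genome.counts, pseudocount)
    kl = max(kl, 0.0)  # guard against float round-off on identical profiles
    return DivergenceResult(
        region_id=region.source_id,
        genome_id=genome.source_id,
        method=method,
        kl_nats=kl,
        score01=score01_from_kl(kl),
    )


KL_TABLE_COLUMNS = ["genome_id", "operon_id", "method", "kl_nats", "score01"]


def operon_kl_table(
    genomes: Sequence[GenomeRecord],
    loci: Sequence[OperonLocus],
    methods: Sequence[str] = ("tetra", "codon"),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One KL row per (operon, method).

    ``tetra`` compares the spanning operon locus to the whole genome using
    reverse-complement-extended tetranucleotide profiles; ``codon`` compares
    the operon's concatenated CDS to the concatenated CDS of every annotated
    gene in the genome.  The genome profile always includes the operon.
    """
    by_id = {g.id: g for g in genomes}
    rows = []
    for locus in loci:
        if locus.genome_id not in by_id:
            raise ValueError(f"locus {locus.operon_id}: unknown genome {locus.genome_id}")
        genome = by_id[locus.genome_id]
        for method in methods:
            if method == "tetra":
                region = kmer_profile(
                    operon_sequence(genome, locus, "spanning"),
                    k=4,
                    source_id=locus.operon_id,
                )
                whole = kmer_profile(
                    genome.sequence, k=4, source_id=genome.id, source_kind="genome"
                )
            elif method == "codon":
                from .composition import codon_profile

                if not genome.features:
                    raise ValueError(
                        f"genome {genome.id} has no CDS features; codon method "
                        "needs annotated coding genes"
                    )
                region = codon_profile(
                    [cds_sequence(genome, f) for _, f in locus.genes],
                    source_id=locus.operon_id,
                )
                whole = codon_profile(
                    [cds_sequence(genome, f) for f in genome.features],
                    source_id=genome.id,
                    source_kind="genome",
                )
            else:
                raise ValueError(f"unknown method {method!r}")
            res = kl_divergence(region, whole, pseudocount, method=method)
            rows.append(
                {
                    "genome_id": genome.id,
                    "operon_id": locus.operon_id,
                    "method": method,
                    "kl_nats": res.kl_nats,
                    "score01": res.score01,
                }
            )
    df = pd.DataFrame(rows, columns=KL_TABLE_COLUMNS)
    return df.sort_values(["genome_id", "operon_id", "method"]).reset_index(drop=True)


def _combined_weights(ks: Sequence[int]) -> np.ndarray:
    w = np.array([4.0 ** -(k - 2) for k in ks])
    return w / w.sum()


def window_scan(
    genome: GenomeRecord,
    window: int = 2500,
    step: int = 500,
    k_range: tuple[int, int] = (2, 8),
    pseudocount: float = 1.0,
) -> list[WindowScore]:
    """Per-window multi-k KL of window composition versus the whole genome.

    Windows tile the genome with the given step; a final partial window is
    kept if it is at least half a window long.  k-mer counts use the
    reverse-complement extension throughout.
    """
    n = len(genome.sequence)
    if window > n:
        raise ValueError(f"window ({window}) exceeds genome length ({n})")
    if step < 1:
        raise ValueError("step must be >= 1")
    kmin, kmax = k_range
    ks = list(range(kmin, kmax + 1))
    weights = _combined_weights(ks)

    codes = encode_dna(genome.sequence)
    # Smoothed whole-genome log-frequencies per k, computed once.
    genome_logq: dict[int, np.ndarray] = {}
    for k in ks:
        gc = count_kmers(codes, k).astype(float) + pseudocount
        genome_logq[k] = np.log(gc / gc.sum())

    starts = list(range(0, n - window + 1, step))
    last_end = starts[-1] + window if starts else 0
    if n - last_end >= window / 2:
        starts.append(last_end)

    scores: list[WindowScore] = []
    for s in starts:
        e = min(s + window, n)
        per_k: dict[int, float] = {}
        for k in ks:
            wc = count_kmers(codes[s:e], k).astype(float) + pseudocount
            p = wc / wc.sum()
            per_k[k] = float(np.sum(p * (np.log(p) - genome_logq[k])))
        combined = float(np.dot(weights, [per_k[k] for k in ks]))
        scores.append(WindowScore(start=s, end=e, combined_kl=combined, per_k=per_k))
    return scores


def _two_means_split(values: np.ndarray) -> tuple[float, np.ndarray]:
    """Exact 1-D 2-means: returns (threshold, upper-cluster mask).

    The optimal 2-means partition of scalars is a sorted split; all splits
    are scored by within-cluster sum of squares via prefix sums.
    """
    order = np.argsort(values)
    v = values[order]
    n = len(v)
    csum = np.cumsum(v)
    csum2 = np.cumsum(v * v)
    best_sse, best_i = np.inf, 1
    for i in range(1, n):  # lower cluster = v[:i]
        sse_lo = csum2[i - 1] - csum[i - 1] ** 2 / i
        hi_sum = csum[-1] - csum[i - 1]
        hi_sum2 = csum2[-1] - csum2[i - 1]
        sse_hi = hi_sum2 - hi_sum**2 / (n - i)
        sse = sse_lo + sse_hi
        if sse < best_sse - 1e-15:
            best_sse, best_i = sse, i
    threshold = 0.5 * (v[best_i - 1] + v[best_i])
    return threshold, values > threshold


def call_alien_regions(
    scores: Sequence[WindowScore],
    operons: Sequence[OperonLocus] = (),
) -> list[AlienRegionCall]:
    """Merge supra-threshold windows into alien-region calls.

    The threshold is the boundary of an exact 2-means split of the combined
    KL values, accepted only if the upper cluster's mean exceeds the overall
    mean by two overall standard deviations (effect-size guard against
    splitting pure noise).  Overlapping/contiguous flagged windows merge;
    each call lists the operon ids it intersects.
    """
    if len(scores) < 10:
        raise ValueError(
            "fewer than 10 windows: scan too short for thresholding; use "
            "operon_kl_table for direct region-vs-genome divergence"
        )
    values = np.array([s.combined_kl for s in scores])
    if np.allclose(values, values[0]):
        return []
    threshold, upper = _two_means_split(values)
    mu, sd = values.mean(), values.std()
    if values[upper].size == 0 or values[upper].mean() <= mu + 2 * sd:
        return []

    calls: list[AlienRegionCall] = []
    cur: AlienRegionCall | None = None
    for sc, flag in zip(scores, upper):
        if not flag:
            continue
        if cur is not None and sc.start <= cur.end:
            cur.end = max(cur.end, sc.end)
            cur.peak_score = max(cur.peak_score, sc.combined_kl)
        else:
            cur = AlienRegionCall(
                start=sc.start, end=sc.end, peak_score=sc.combined_kl, threshold=threshold
            )
            calls.append(cur)
    for call in calls:
        call.overlapping_operons = sorted(
            locus.operon_id
            for locus in operons
            if min(call.end, locus.span[1]) - max(call.start, locus.span[0]) > 0
        )
    return calls


def calls_to_bed(calls: Sequence[AlienRegionCall], genome_id: str, path) -> None:
    """Write calls as BED (0-based half-open; score scaled to 0-1000)."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            score = int(round(1000 * score01_from_kl(c.peak_score)))
            fh.write(
                f"{genome_id}\t{c.start}\t{c.end}\talien_{i + 1}\t{score}\t.\n"
            )
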