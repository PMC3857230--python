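"""Fragment-level annotation and community/feature association tests.

Binary annotations (centromeres, telomeres, tRNAs, factor binding sites)
are mapped onto fragments by a non-zero-overlap criterion — any shared
base pair labels the fragment — or, for genes, by containment of the
transcription start site. Continuous tracks (replication timing %, ChIP
read counts) are summarised per fragment as the unweighted mean of
overlapping interval values, and ChIP enrichment as the log2 ratio of
ChIP to control counts.

Association between community membership and a binary feature uses the
two-tailed Fisher's exact test on the 2x2 table (in community x has
feature) over the analysed network's fragments; families of factor
tests within one community are corrected with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureTrack, FragmentSet, SignalTrack

__all__ = [
    "label_by_overlap",
    "mean_signal",
    "log2_ratio",
    "fisher_enrichment",
    "bh_fdr",
    "EnrichmentResult",
    "enrichment_table",
]

logger = logging.getLogger(__name__)


def _trees(intervals: Iterable[tuple], chroms: set[str], track_name: str):
    trees: dict[str, IntervalTree] = {}
    skipped = 0
    for item in intervals:
        chrom, start, end = item[0], item[1], item[2]
        if chrom not in chroms:
            skipped += 1
            continue
        payload = item[3] if len(item) > 3 else None
        trees.setdefault(chrom, IntervalTree()).addi(start, end, payload)
    if skipped:
        logger.info(
            "track %s: %d intervals on chromosomes absent from the fragment set",
            track_name, skipped,
        )
    return trees


def label_by_overlap(
    fragments: FragmentSet, track: FeatureTrack, mode: str = "overlap"
) -> dict[str, bool]:
    """Binary per-fragment labels from a feature track.

    mode="overlap": label True iff the fragment shares >= 1 bp with any
    track interval (half-open intervals, so [a,b) and [b,c) do not
    touch). mode="tss": gene-style assignment — label True iff any
    interval's start coordinate (the transcription start site) lies
    inside the fragment. Track intervals on chromosomes absent from the
    fragment set are skipped with a logged count.
    """
    if mode not in ("overlap", "tss"):
        raise ValueError(f"mode must be 'overlap' or 'tss', got {mode!r}")
    chroms = set(f.chrom for f in fragments)
    trees = _trees(track.intervals, chroms, track.name)
    labels: dict[str, bool] = {}
    for frag in fragments:
        tree = trees.get(frag.chrom)
        if tree is None:
            labels[frag.id] = False
        elif mode == "overlap":
            labels[frag.id] = bool(tree.overlap(frag.start, frag.end))
        else:
            hits = tree.overlap(frag.start, frag.end)
            labels[frag.id] = any(frag.start <= iv.begin < frag.end for iv in hits)
    return labels


def mean_signal(fragments: FragmentSet, track: SignalTrack) -> dict[str, float]:
    """Unweighted mean of track values overlapping each fragment.

    Fragments overlapping no interval map to NaN (missing). An interval
    spanning two fragments contributes its full value to both means —
    containment is not required, only non-zero overlap.
    """
    chroms = set(f.chrom for f in fragments)
    trees = _trees(track.intervals, chroms, track.name)
    values: dict[str, float] = {}
    for frag in fragments:
        tree = trees.get(frag.chrom)
        hits = tree.overlap(frag.start, frag.end) if tree is not None else ()
        if hits:
            values[frag.id] = float(np.mean([iv.data for iv in hits]))
        else:
            values[frag.id] = math.nan
    return values


def log2_ratio(
    chip_counts: Mapping[str, float],
    control_counts: Mapping[str, float],
    pseudocount: float = 0.5,
    libsize_normalize: bool = True,
) -> dict[str, float]:
    """Per-fragment log2(ChIP / control) enrichment.

    With ``libsize_normalize`` the ChIP counts are scaled by
    s = total(control) / total(ChIP) before the ratio, so a flat
    enrichment of 0 means equal relative coverage regardless of
    sequencing depth. ``pseudocount`` stabilises fragments with zero
    counts.
    """
    if set(chip_counts) != set(control_counts):
        raise ValueError("chip and control counts must cover the same fragments")
    chip_total = float(sum(chip_counts.values()))
    control_total = float(sum(control_counts.values()))
    if chip_total == 0 and control_total == 0:
        raise ValueError("both libraries are empty")
    s = (control_total / chip_total) if (libsize_normalize and chip_total > 0) else 1.0
    out: dict[str, float] = {}
    for frag_id, chip in chip_counts.items():
        control = control_counts[frag_id]
        if chip < 0 or control < 0:
            raise ValueError(f"negative count at fragment {frag_id!r}")
        num = chip * s + pseudocount
        den = control + pseudocount
        if den == 0:
            out[frag_id] = math.nan if num == 0 else math.inf
        else:
            out[frag_id] = math.log2(num / den) if num > 0 else -math.inf
    return out


@dataclass
class EnrichmentResult:
    """Two-tailed Fisher's exact test of one feature vs one community.

    Counts follow (in-community & has-feature, in & lacks, out & has,
    out & lacks); ``degenerate`` flags a zero margin, where p = 1 by
    convention. ``fdr`` is filled in by :func:`enrichment_table` when the
    test belongs to a corrected factor family.
    """

    community: object
    feature: str
    counts: tuple[int, int, int, int]
    odds_ratio: float
    p: float
    fdr: float | None = None
    degenerate: bool = False


def fisher_enrichment(
    labels: Mapping[str, bool],
    membership: Mapping[str, bool],
    feature: str = "feature",
    community: object = None,
) -> EnrichmentResult:
    """Association between a binary feature and community membership.

    The universe is the key set of ``membership`` (the fragments of the
    analysed network); ``labels`` must cover it. The p-value is the
    probability-mass two-tailed Fisher p: the sum of hypergeometric
    probabilities of all tables with the same margins whose probability
    does not exceed the observed table's.
    """
    a = b = c = d = 0
    for frag_id, in_com in membership.items():
        if frag_id not in labels:
            raise KeyError(f"fragment {frag_id!r} has no feature label")
        has = bool(labels[frag_id])
        if in_com and has:
            a += 1
        elif in_com:
            b += 1
        elif has:
            c += 1
        else:
            d += 1
    table = np.array([[a, b], [c, d]])
    degenerate = any(margin == 0 for margin in (a + b, c + d, a + c, b + d))
    if degenerate:
        p = 1.0
        logger.info("zero margin for feature %r / community %r; p = 1", feature, community)
    else:
        p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    odds = (a * d) / (b * c) if b * c > 0 else math.inf if a * d > 0 else math.nan
    return EnrichmentResult(
        community=community,
        feature=feature,
        counts=(a, b, c, d),
        odds_ratio=odds,
        p=min(p, 1.0),
        degenerate=degenerate,
    )


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * M / j over the sorted p-values, capped
    at 1; monotone in p.
    """
    pvals = list(pvalues)
    if not pvals:
        return []
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    return list(multipletests(pvals, method="fdr_bh")[1])


def enrichment_table(
    membership_by_community: Mapping[object, Mapping[str, bool]],
    feature_labels: Mapping[str, Mapping[str, bool]],
    fdr_families: Iterable[str] = (),
) -> list[EnrichmentResult]:
    """Test every (community, feature) pair.

    ``membership_by_community`` maps community id -> per-fragment
    membership indicator over the network universe.
    ``feature_labels`` maps feature name -> per-fragment binary labels.
    Features named in ``fdr_families`` (e.g. the panel of transcription
    factors) are BH-corrected together within each community; all other
    features (centromeres, telomeres, tRNAs) report raw p only.
    """
    family = set(fdr_families)
    results: list[EnrichmentResult] = []
    for com_id, membership in membership_by_community.items():
        com_results = [
            fisher_enrichment(labels, membership, feature=name, community=com_id)
            for name, labels in feature_labels.items()
        ]
        fam = [r for r in com_results if r.feature in family]
        if fam:
            qvals = bh_fdr([r.p for r in fam])
            for r, q in zip(fam, qvals):
                r.fdr = q
        results.extend(com_results)
    return results
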