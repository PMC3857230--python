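"""Synthetic rosette-genome generator.

Budding-yeast-like nuclear organization is emulated as a rosette:
centromeres from all chromosomes cluster at one pole, chromosome arms
radiate outward in strata of increasing centromere distance, and
telomeres form their own cross-chromosome cluster. The generator plants
that organization in a multi-chromosome fragment map and draws Bernoulli
interaction calls per fragment pair with class-specific probabilities,
so every pipeline stage — network construction, cliques, community
detection, null calibration, recapitulation, enrichment — can be tested
end to end without external data.

Interaction FDR scores are tier labels, not outputs of a contact
probability model: each realized edge is assigned a sub-0.0001 or
sub-0.01 score so that thresholding at the two cutoffs yields nested
networks by construction (the stringent network is a subnetwork of the
lenient one on every draw).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Fragment, FragmentSet, FeatureTrack, InteractionRecord, SignalTrack

__all__ = ["RosetteSpec", "SyntheticTruth", "generate", "generate_tracks"]

STRICT_FDR = 1e-4   # stringent-tier scores fall below this
LENIENT_FDR = 1e-2  # all scores fall below this


def _default_tiers() -> dict[str, float]:
    # fraction of each edge class scored in the stringent tier; noise
    # contacts rarely reach high confidence
    return {
        "cen": 0.6,
        "stratum": 0.6,
        "telomere": 0.6,
        "adjacent": 0.6,
        "noise": 0.1,
    }


@dataclass
class RosetteSpec:
    """Parameters of the planted rosette genome.

    Eight chromosomes of 50 fragments (4 kb each — the scale of a
    typical HindIII restriction fragment) put the generator at a few
    hundred nodes, large enough for every statistic yet fast enough for
    replicated runs. The centromere sits mid-chromosome; fragments
    within ``stratum_bounds[0]`` of it form the centromeric stratum, the
    remaining bounds delimit arm strata, and ``telomere_fragments``
    fragments at each chromosome end form the telomere cluster.

    Edge probabilities order the architecture: centromere-cluster
    contacts (p_cen) are densest, same-stratum contacts (p_stratum,
    attenuated by ``stratum_decay`` per additional stratum away from the
    centromere — rosette contact density falls off along the arms) and
    telomere-cluster contacts (p_telomere) intermediate, linear-neighbour
    contacts (p_intra_adjacent) strong but intra-chromosomal only, and
    uniform background noise (p_noise) sparse. A detectable rosette needs
    p_cen > p_stratum > p_noise.
    """

    n_chromosomes: int = 8
    fragments_per_chromosome: int = 50
    fragment_length: int = 4000
    centromere_index: int = 25
    stratum_bounds: tuple[int, ...] = (3, 12)
    telomere_fragments: int = 2
    p_cen: float = 0.25
    p_stratum: float = 0.06
    stratum_decay: float = 0.5
    p_telomere: float = 0.15
    p_intra_adjacent: float = 0.6
    p_noise: float = 0.002
    fdr_tiers: dict = field(default_factory=_default_tiers)
    seed: int = 0

    def __post_init__(self):
        probs = (self.p_cen, self.p_stratum, self.p_telomere,
                 self.p_intra_adjacent, self.p_noise)
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("edge probabilities must lie in [0, 1]")
        # degenerate equalities (e.g. all-zero arms) are allowed for
        # limit-case testing; a detectable rosette needs the strict order
        if not (self.p_cen >= self.p_stratum >= self.p_noise and self.p_cen > self.p_noise):
            raise ValueError("need p_cen >= p_stratum >= p_noise (p_cen > p_noise)")
        if not (0.0 < self.stratum_decay <= 1.0):
            raise ValueError("stratum_decay must be in (0, 1]")
        arm = max(self.centromere_index,
                  self.fragments_per_chromosome - 1 - self.centromere_index)
        if not all(0 < b < arm for b in self.stratum_bounds):
            raise ValueError("stratum bounds must fall inside the chromosome arm")
        if list(self.stratum_bounds) != sorted(set(self.stratum_bounds)):
            raise ValueError("stratum bounds must be strictly increasing")
        for cls, frac in self.fdr_tiers.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fdr tier fraction for {cls!r} outside [0, 1]")

    @property
    def n_strata(self) -> int:
        return len(self.stratum_bounds) + 1


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded for recovery tests.

    ``labels`` holds the planted community of each fragment ("cen",
    "arm1", ..., "tel"); ``stratum_index`` its centromere-distance
    stratum (0 = centromeric); ``cross_degree`` its realized number of
    cross-chromosome interaction partners. The signal-generator
    parameters (replication base/slope/noise, ChIP rates, planted-factor
    placement rates) are carried so recovery tests know what was
    planted.
    """

    labels: dict[str, str]
    stratum_index: dict[str, int]
    cross_degree: dict[str, int]
    seed: int
    rep_base: float = 80.0
    rep_slope: float = 12.0
    rep_sigma: float = 2.5
    chip_base: float = 10.0
    chip_slope: float = 3.0
    control_rate: float = 20.0
    factor_rho_in: float = 0.6
    factor_rho_out: float = 0.05
    factor_community: str = "cen"


def _layout(spec: RosetteSpec):
    """Fragment ids with chromosome, index, stratum and planted label."""
    frags = FragmentSet()
    meta: dict[str, tuple[str, int, int, str]] = {}
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        for i in range(spec.fragments_per_chromosome):
            frag_id = f"{chrom}_f{i:03d}"
            start = i * spec.fragment_length
            frags.add(Fragment(frag_id, chrom, start, start + spec.fragment_length))
            d = abs(i - spec.centromere_index)
            stratum = sum(d > b for b in spec.stratum_bounds)
            telomeric = (
                i < spec.telomere_fragments
                or i >= spec.fragments_per_chromosome - spec.telomere_fragments
            )
            if telomeric:
                label = "tel"
            elif stratum == 0:
                label = "cen"
            else:
                label = f"arm{stratum}"
            meta[frag_id] = (chrom, i, stratum, label)
    return frags, meta


def _pair_class(meta_a, meta_b) -> str:
    chrom_a, i_a, _, lab_a = meta_a
    chrom_b, i_b, _, lab_b = meta_b
    same_chrom = chrom_a == chrom_b
    if same_chrom and abs(i_a - i_b) == 1:
        return "adjacent"
    if not same_chrom:
        if lab_a == lab_b == "cen":
            return "cen"
        if lab_a == lab_b == "tel":
            return "telomere"
    if lab_a == lab_b and lab_a.startswith("arm"):
        return "stratum"
    return "noise"


def generate(spec: RosetteSpec) -> tuple[FragmentSet, list[InteractionRecord], SyntheticTruth]:
    """Draw one synthetic genome: fragments, scored interactions, truth.

    Every unordered fragment pair is an independent Bernoulli draw with
    the probability of its contact class; each realized edge receives an
    FDR score from its class's tier mix. Identical specs (including the
    seed) reproduce the interaction table exactly.
    """
    rng = np.random.default_rng(spec.seed)
    frags, meta = _layout(spec)
    ids = frags.ids()
    prob = {
        "cen": spec.p_cen,
        "stratum": spec.p_stratum,
        "telomere": spec.p_telomere,
        "adjacent": spec.p_intra_adjacent,
        "noise": spec.p_noise,
    }
    records: list[InteractionRecord] = []
    cross_degree = {frag_id: 0 for frag_id in ids}
    n_expected = 0.0
    for ai in range(len(ids)):
        for bi in range(ai + 1, len(ids)):
            a, b = ids[ai], ids[bi]
            cls = _pair_class(meta[a], meta[b])
            p = prob[cls]
            if cls == "stratum":
                p *= spec.stratum_decay ** (meta[a][2] - 1)
            n_expected += p
            if p == 0.0 or rng.random() >= p:
                continue
            strict_frac = spec.fdr_tiers.get(cls, 0.0)
            if rng.random() < strict_frac:
                fdr = rng.uniform(1e-6, STRICT_FDR * 0.99)
            else:
                fdr = rng.uniform(STRICT_FDR * 1.01, LENIENT_FDR * 0.99)
            inter = meta[a][0] != meta[b][0]
            records.append(
                InteractionRecord(a, b, float(fdr), "inter" if inter else "intra")
            )
            if inter:
                cross_degree[a] += 1
                cross_degree[b] += 1
    if n_expected == 0:
        raise ValueError("spec yields an expected edge count of zero")
    truth = SyntheticTruth(
        labels={frag_id: meta[frag_id][3] for frag_id in ids},
        stratum_index={frag_id: meta[frag_id][2] for frag_id in ids},
        cross_degree=cross_degree,
        seed=spec.seed,
    )
    return frags, records, truth


def generate_tracks(
    truth: SyntheticTruth, fragments: FragmentSet, seed: int | None = None
) -> dict:
    """Feature and signal tracks correlated with the planted structure.

    Returns a dict with keys: "replication" (percent replicated,
    decreasing with centromere-distance stratum plus Gaussian noise),
    "chip" / "control" (Poisson read counts; the ChIP rate increases
    with realized cross-chromosome degree, emulating a cohesin-like
    factor, the control rate is flat), "centromeres" / "telomeres"
    (point-like feature intervals at the planted positions), and
    "planted_factor" (binding-site intervals placed inside fragments of
    ``truth.factor_community`` at rate rho_in and elsewhere at rho_out).
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    replication = SignalTrack("replication", [])
    chip = SignalTrack("chip", [])
    control = SignalTrack("control", [])
    centromeres = FeatureTrack("centromeres", [])
    telomeres = FeatureTrack("telomeres", [])
    factor = FeatureTrack("planted_factor", [])
    chrom_max: dict[str, int] = {}
    for frag in fragments:
        chrom_max[frag.chrom] = max(chrom_max.get(frag.chrom, 0), frag.end)
    cen_frags: dict[str, list] = {}
    for frag in fragments:
        label = truth.labels[frag.id]
        stratum = truth.stratum_index[frag.id]
        rep = truth.rep_base - truth.rep_slope * stratum + rng.normal(0.0, truth.rep_sigma)
        replication.intervals.append((frag.chrom, frag.start, frag.end, float(rep)))
        lam = truth.chip_base + truth.chip_slope * truth.cross_degree[frag.id]
        chip.intervals.append(
            (frag.chrom, frag.start, frag.end, float(rng.poisson(lam)))
        )
        control.intervals.append(
            (frag.chrom, frag.start, frag.end, float(rng.poisson(truth.control_rate)))
        )
        mid = (frag.start + frag.end) // 2
        if label == "cen":
            cen_frags.setdefault(frag.chrom, []).append(frag)
        rho = truth.factor_rho_in if label == truth.factor_community else truth.factor_rho_out
        if rng.random() < rho:
            factor.intervals.append((frag.chrom, mid, mid + 200))
    for chrom, members in cen_frags.items():
        # one point-like centromere per chromosome, at the middle of its
        # centromeric stratum
        members.sort(key=lambda f: f.start)
        cen = members[len(members) // 2]
        mid = (cen.start + cen.end) // 2
        centromeres.intervals.append((chrom, mid, mid + 120))
    for chrom, end in chrom_max.items():
        telomeres.intervals.append((chrom, 0, 300))
        telomeres.intervals.append((chrom, end - 300, end))
    return {
        "replication": replication,
        "chip": chip,
        "control": control,
        "centromeres": centromeres,
        "telomeres": telomeres,
        "planted_factor": factor,
    }
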