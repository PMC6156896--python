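"""Synthetic cohort generator: pedigrees, gene-dropped genotypes with planted
homozygous segments, TG-response phenotypes with a planted window-level
effect, and two-probe-type methylation with a planted cis link.

Everything is deterministic given the config seed. Scales are desk-sized by
default (60 families of ~5, 2 chromosomes x 2000 SNPs over 60 Mb) so the
full pipeline runs in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MethylationSet, PhenotypeTable
from .methylation import beta_to_m, m_to_beta


@dataclass
class RohPlanEntry:
    carrier_fraction: float
    length_bp: int
    chrom_index: int = 0
    start_bp: int | None = None    # random when None
    is_effect_segment: bool = False


@dataclass
class TgModel:
    beta_hd: float = -40.0
    intercept: float = -20.0
    covariate_effects: dict = field(default_factory=lambda: {
        "sex": 5.0, "age": -0.2, "smoking": 4.0, "atp": 3.0, "idf": 3.0,
        "center_B": 2.0,
    })
    family_sd: float = 10.0
    residual_sd: float = 20.0
    baseline_mean: float = 180.0
    baseline_sd: float = 25.0
    visit_jitter_sd: float = 5.0


@dataclass
class MethModel:
    n_cpgs: int = 800
    state_weights: tuple = (0.4, 0.2, 0.4)
    state_shapes: tuple = ((2.0, 20.0), (5.0, 5.0), (20.0, 2.0))
    type2_fraction: float = 0.5
    compression: float = 0.7       # type-II logit-scale shrink factor
    cis_effect: float = 1.0        # M-units per unit window intensity
    n_cis_cpgs: int = 3
    response_noise_sd: float = 0.2


@dataclass
class SimulationConfig:
    n_families: int = 60
    offspring_choices: tuple = (2, 3, 4)
    n_chromosomes: int = 2
    snps_per_chromosome: int = 2000
    chromosome_length_bp: int = 60_000_000
    maf_low: float = 0.01
    maf_high: float = 0.5
    roh_plan: list = field(default_factory=lambda: [
        RohPlanEntry(carrier_fraction=0.25, length_bp=10_000_000,
                     chrom_index=0, start_bp=20_000_001, is_effect_segment=True),
    ])
    #: span of the region whose homozygote fraction drives the TG effect;
    #: matches the default analysis window span (5% of the chromosome)
    effect_window_bp: int = 2_000_000
    tg_model: TgModel = field(default_factory=TgModel)
    meth_model: MethModel = field(default_factory=MethModel)
    seed: int = 0

    def validate(self) -> None:
        for e in self.roh_plan:
            if not 0 <= e.carrier_fraction <= 1:
                raise ValueError("carrier_fraction outside [0,1]")
            if e.length_bp <= 0:
                raise ValueError("segment length must be positive")
            if e.length_bp > self.chromosome_length_bp:
                raise ValueError("segment exceeds chromosome length")
        w = self.meth_model.state_weights
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("methylation state weights must sum to 1")


@dataclass
class PlantedSegment:
    sample: str
    chrom: str
    start: int
    end: int
    is_effect_segment: bool


@dataclass
class SyntheticTruth:
    segments: list[PlantedSegment]
    beta_hd: float
    window_intensity: np.ndarray       # per-sample true homozygote fraction
    effect_span: tuple | None          # (chrom, start, end) of the effect segment
    effect_region: tuple | None        # central subregion driving the TG effect
    family_effects: dict               # pedigree -> random effect
    cis_links: list                    # (cpg_id, effect_size)
    seed: int


def _pedigree(config: SimulationConfig, rng: np.random.Generator):
    """Sample ids, pedigree ids, and parent index pairs (None for founders)."""
    samples, peds, parents = [], [], []
    for f in range(config.n_families):
        fam = f"F{f:03d}"
        base = len(samples)
        samples += [f"{fam}_P1", f"{fam}_P2"]
        peds += [fam, fam]
        parents += [None, None]
        for o in range(int(rng.choice(config.offspring_choices))):
            samples.append(f"{fam}_O{o + 1}")
            peds.append(fam)
            parents.append((base, base + 1))
    return samples, np.array(peds, dtype=object), parents


def _unique_positions(rng: np.random.Generator, m: int, length: int) -> np.ndarray:
    """m distinct sorted positions in [1, length] without materializing the range."""
    if m > length:
        raise ValueError("more SNPs than base pairs")
    pos = np.unique(rng.integers(1, length + 1, size=m))
    while len(pos) < m:
        extra = rng.integers(1, length + 1, size=m - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos)


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Founder haplotypes by Bernoulli(MAF), offspring by gene dropping,
    then planted homozygous segments imposed on the chosen carriers."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples, peds, parents = _pedigree(config, rng)
    n_samples = len(samples)
    n_chr, m = config.n_chromosomes, config.snps_per_chromosome
    n_snps = n_chr * m

    maf = rng.uniform(config.maf_low, config.maf_high, size=n_snps)
    chrom = np.repeat([f"chr{c + 1}" for c in range(n_chr)], m).astype(object)
    pos = np.concatenate([
        _unique_positions(rng, m, config.chromosome_length_bp)
        for _ in range(n_chr)
    ]).astype(np.int64)

    haps = np.zeros((n_samples, 2, n_snps), dtype=np.int8)
    for s, par in enumerate(parents):
        if par is None:
            haps[s] = rng.random((2, n_snps)) < maf
        else:
            for which, p_idx in enumerate(par):
                pick = rng.integers(0, 2, size=n_snps)
                haps[s, which] = haps[p_idx, pick, np.arange(n_snps)]
    geno = haps.sum(axis=1).astype(np.int8)

    segments: list[PlantedSegment] = []
    effect_span = None
    for entry in config.roh_plan:
        c = f"chr{entry.chrom_index + 1}"
        start = entry.start_bp if entry.start_bp is not None else int(
            rng.integers(1, config.chromosome_length_bp - entry.length_bp + 1))
        end = start + entry.length_bp - 1
        n_carriers = int(round(entry.carrier_fraction * n_samples))
        carriers = rng.choice(n_samples, size=n_carriers, replace=False)
        in_seg = (chrom == c) & (pos >= start) & (pos <= end)
        # homozygote of the more frequent allele of each SNP
        hom_code = np.where(maf <= 0.5, 0, 2).astype(np.int8)
        for s in carriers:
            geno[s, in_seg] = hom_code[in_seg]
            segments.append(PlantedSegment(samples[s], c, start, end,
                                           entry.is_effect_segment))
        if entry.is_effect_segment:
            effect_span = (c, start, end)

    gm = GenotypeMatrix(
        samples=samples, pedigree=peds, genotypes=geno,
        snp_ids=np.array([f"snp{i}" for i in range(n_snps)], dtype=object),
        chrom=chrom, pos=pos,
        alleles=np.array([("A", "G")] * n_snps, dtype=object),
    )

    if effect_span is not None:
        c, start, end = effect_span
        # effect quantity = homozygote fraction over a window-sized central
        # subregion, so the window-level estimator can recover beta_hd
        mid = (start + end) // 2
        half = config.effect_window_bp // 2
        lo, hi = max(start, mid - half), min(end, mid + half)
        in_eff = (chrom == c) & (pos >= lo) & (pos <= hi)
        window_intensity = (geno[:, in_eff] != 1).mean(axis=1)
        effect_region = (c, lo, hi)
    else:
        window_intensity = np.zeros(n_samples)
        effect_region = None

    truth = SyntheticTruth(
        segments=segments, beta_hd=config.tg_model.beta_hd,
        window_intensity=window_intensity, effect_span=effect_span,
        effect_region=effect_region,
        family_effects={}, cis_links=[], seed=config.seed,
    )
    return gm, truth


def simulate_phenotypes(gm: GenotypeMatrix, truth: SyntheticTruth,
                        config: SimulationConfig) -> PhenotypeTable:
    """TG visits constructed so mean(V3,V4) - mean(V1,V2) equals the planted
    linear model exactly (up to the non-negativity floor on raw TG)."""
    tm = config.tg_model
    rng = np.random.default_rng(config.seed + 1)
    n = gm.n_samples
    sex = rng.integers(0, 2, n)
    age = rng.uniform(20, 70, n)
    center = rng.choice(["A", "B"], n)
    smoking = rng.integers(0, 2, n)
    atp = rng.integers(0, 2, n)
    idf = rng.integers(0, 2, n)

    fams = sorted(set(gm.pedigree))
    fam_eff = {f: rng.normal(0, tm.family_sd) for f in fams}
    truth.family_effects = fam_eff

    eff = tm.covariate_effects
    response = (
        tm.intercept
        + tm.beta_hd * truth.window_intensity
        + eff.get("sex", 0) * sex + eff.get("age", 0) * age
        + eff.get("smoking", 0) * smoking + eff.get("atp", 0) * atp
        + eff.get("idf", 0) * idf
        + eff.get("center_B", 0) * (center == "B")
        + np.array([fam_eff[f] for f in gm.pedigree])
        + rng.normal(0, tm.residual_sd, n)
    )
    base = rng.normal(tm.baseline_mean, tm.baseline_sd, n)
    d_pre = rng.normal(0, tm.visit_jitter_sd, n)
    d_post = rng.normal(0, tm.visit_jitter_sd, n)
    tg1, tg2 = base + d_pre, base - d_pre
    tg3, tg4 = base + response + d_post, base + response - d_post
    # raw TG cannot be negative; the floor breaks exactness only in rare tails
    tg = np.clip(np.column_stack([tg1, tg2, tg3, tg4]), 0.0, None)
    return PhenotypeTable(pd.DataFrame({
        "sample": gm.samples, "pedigree": gm.pedigree,
        "tg1": tg[:, 0], "tg2": tg[:, 1], "tg3": tg[:, 2], "tg4": tg[:, 3],
        "sex": sex, "age": age, "center": center, "smoking": smoking,
        "atp": atp, "idf": idf,
    }))


def simulate_methylation(gm: GenotypeMatrix, truth: SyntheticTruth,
                         config: SimulationConfig) -> MethylationSet:
    """Three-state beta mixture per CpG; type-II betas compressed toward 0.5
    on the M scale; cis-linked CpGs get a visit-4 M shift proportional to
    the sample's true window intensity."""
    mm = config.meth_model
    if abs(sum(mm.state_weights) - 1.0) > 1e-9:
        raise ValueError("state weights must sum to 1")
    rng = np.random.default_rng(config.seed + 2)
    n_cpg, n_samples = mm.n_cpgs, gm.n_samples

    chroms = gm.chromosomes()
    cpg_chrom = rng.choice(np.array(chroms, dtype=object), n_cpg)
    cpg_pos = rng.integers(1, config.chromosome_length_bp, n_cpg)
    probe_type = np.where(rng.random(n_cpg) < mm.type2_fraction, "II", "I").astype(object)
    states = rng.choice(len(mm.state_weights), size=n_cpg, p=mm.state_weights)

    # place cis CpGs inside the effect segment, forced to probe type I so
    # the planted effect is not entangled with the type-II bias
    cis_links = []
    if truth.effect_span is not None and mm.n_cis_cpgs > 0:
        c, start, end = truth.effect_span
        for i in range(min(mm.n_cis_cpgs, n_cpg)):
            cpg_chrom[i] = c
            cpg_pos[i] = rng.integers(start, end + 1)
            probe_type[i] = "I"
            states[i] = 1
            cis_links.append((f"cg{i:06d}", mm.cis_effect))
    truth.cis_links = cis_links

    a = np.array([mm.state_shapes[s][0] for s in states])
    b = np.array([mm.state_shapes[s][1] for s in states])
    beta2 = rng.beta(a[:, None], b[:, None], size=(n_cpg, n_samples))
    beta2 = np.clip(beta2, 1e-6, 1 - 1e-6)
    m2 = beta_to_m(beta2)
    m4 = m2 + rng.normal(0, mm.response_noise_sd, size=(n_cpg, n_samples))

    is2 = probe_type == "II"
    m2[is2] *= mm.compression
    m4[is2] *= mm.compression

    for i, (_, effect) in enumerate(cis_links):
        m4[i] += effect * truth.window_intensity

    return MethylationSet(
        cpg_ids=np.array([f"cg{i:06d}" for i in range(n_cpg)], dtype=object),
        chrom=cpg_chrom, pos=cpg_pos.astype(np.int64), probe_type=probe_type,
        samples=list(gm.samples),
        beta={2: m_to_beta(m2), 4: m_to_beta(m4)},
    )


def truth_to_frame(truth: SyntheticTruth) -> dict[str, pd.DataFrame]:
    """Truth sidecar tables for on-disk storage."""
    seg = pd.DataFrame([asdict(s) for s in truth.segments])
    samp = pd.DataFrame({"window_intensity": truth.window_intensity})
    cis = pd.DataFrame(truth.cis_links, columns=["cpg", "effect"])
    meta = pd.DataFrame({
        "beta_hd": [truth.beta_hd], "seed": [truth.seed],
        "effect_chrom": [truth.effect_span[0] if truth.effect_span else ""],
        "effect_start": [truth.effect_span[1] if truth.effect_span else -1],
        "effect_end": [truth.effect_span[2] if truth.effect_span else -1],
    })
    return {"segments": seg, "sample_intensity": samp, "cis_links": cis, "meta": meta}
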