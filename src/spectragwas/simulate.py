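"""Simulation of MAGIC-like genotypes and structured leaf reflectance spectra.

The generator mimics the data-generating process of a multiparent advanced
generation inter-cross (MAGIC) field experiment: a panel of inbred founder
lines is intercrossed into recombinant inbred lines (RILs), each RIL
contributes one plant, and every plant yields a full-range (400-2500 nm)
leaf reflectance spectrum shaped by

* a smooth leaf-like base template (chlorophyll absorption wells, the
  red-edge rise, a NIR plateau and water absorption wells),
* additive effects of planted causal SNPs on contiguous wavelength bands,
* environmental level effects for the field/measurement design factors
  (leaf number LN, replicate set REP, spatial patch BA, day DT, time of
  day CT, maternal origin MO and the LN:REP, LN:BA and DT:CT interactions),
* wavelength-dependent Gaussian noise.

A configurable fraction of samples are "phytometers": tester-genotype
plants whose genetic (dosage) effects are zeroed but which experience the
same environment, so spatial patch effects can be estimated from them.

Every function is deterministic given its ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WAVELENGTH_LO = 400
WAVELENGTH_HI = 2500
WAVELENGTH_GRID = np.arange(WAVELENGTH_LO, WAVELENGTH_HI + 1)

__all__ = [
    "FounderHaplotypes",
    "EffectSpec",
    "CausalSNP",
    "EnvironmentalDesign",
    "TruthRecord",
    "GenotypeMatrix",
    "simulate_founders",
    "simulate_rils",
    "simulate_spectra",
    "base_template",
    "write_vcf",
    "WAVELENGTH_GRID",
]


@dataclass
class FounderHaplotypes:
    """Binary haplotypes of the founder panel.

    alleles is founders x SNPs in {0, 1}; positions are 1-based and strictly
    increasing within each chromosome.
    """

    alleles: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    maf_range: tuple[float, float]

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [f"chr{c}_{p}" for c, p in zip(self.chrom, self.pos)]


@dataclass
class CausalSNP:
    snp_index: int
    band_lo: int
    band_hi: int
    effect: float


@dataclass
class EffectSpec:
    """Planted genetic architecture for simulated spectra.

    Each causal SNP adds ``effect`` reflectance units per alternate allele
    uniformly over its wavelength band [band_lo, band_hi] nm.  Latent factor
    scalings modulate broad leaf features (pigment depth, NIR structure,
    water-well depth, SWIR dry-matter slope) with per-sample Gaussian
    multipliers; they create realistic long-range correlation.
    """

    causal_snps: list[CausalSNP] = field(default_factory=list)
    pigment_sd: float = 0.0
    structure_sd: float = 0.0
    water_sd: float = 0.0
    dry_matter_sd: float = 0.0
    # overall brightness scaling (profile = the base template itself);
    # the dominant axis of between-leaf variation in real spectra
    amplitude_sd: float = 0.0

    def validate(self) -> None:
        for c in self.causal_snps:
            if not (WAVELENGTH_LO <= c.band_lo <= c.band_hi <= WAVELENGTH_HI):
                raise ValueError(
                    f"causal band [{c.band_lo}, {c.band_hi}] outside "
                    f"[{WAVELENGTH_LO}, {WAVELENGTH_HI}] nm grid"
                )
            if not np.isfinite(c.effect):
                raise ValueError("causal effect sizes must be finite")


@dataclass
class EnvironmentalDesign:
    """Sizes and standard deviations of the environmental design terms.

    ``*_sd`` values are in reflectance units; effects are drawn i.i.d.
    Gaussian per factor level (and per interaction cell) and added uniformly
    across the spectrum.
    """

    n_ln: int = 2
    n_rep: int = 2
    n_patch: int = 8
    n_dt: int = 4
    n_ct: int = 3
    n_mo: int = 26
    ln_sd: float = 0.0
    rep_sd: float = 0.0
    patch_sd: float = 0.0
    ln_rep_sd: float = 0.0
    ln_patch_sd: float = 0.0
    dt_sd: float = 0.0
    ct_sd: float = 0.0
    dt_ct_sd: float = 0.0
    mo_sd: float = 0.0


@dataclass
class TruthRecord:
    """Ground truth of one spectra simulation, for downstream verification."""

    causal_snps: list[CausalSNP]
    variance_fractions: dict[str, float]  # environmental terms only
    noise_sd: np.ndarray
    phytometer: np.ndarray
    seed: int
    genetic_fraction: float = 0.0
    noise_fraction: float = 0.0

    def validate(self) -> None:
        total = sum(self.variance_fractions.values())
        if not all(0.0 <= v <= 1.0 for v in self.variance_fractions.values()):
            raise ValueError("variance fractions must lie in [0, 1]")
        if total >= 1.0 + 1e-9:
            raise ValueError("variance fractions must sum to < 1")


@dataclass
class GenotypeMatrix:
    """Additive dosage matrix (samples x SNPs, values in {0, 1, 2})."""

    dosages: np.ndarray
    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [f"chr{c}_{p}" for c, p in zip(self.chrom, self.pos)]


def simulate_founders(
    n_founders: int = 26,
    n_snps: int = 1000,
    n_chrom: int = 12,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    chrom_length: int = 50_000_000,
) -> FounderHaplotypes:
    """Draw i.i.d. binary founder haplotypes with per-SNP allele frequency
    constrained to ``maf_range``.

    For each SNP an alternate-allele count k is chosen uniformly among the
    integers with k/n_founders inside maf_range, then assigned to a random
    founder subset, so observed founder frequencies are inside the range by
    construction.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    rng = np.random.default_rng(seed)

    k_min = int(np.ceil(lo * n_founders - 1e-9))
    k_max = int(np.floor(hi * n_founders + 1e-9))
    k_min = max(k_min, 1)
    if k_min > k_max:
        raise ValueError(
            f"no integer allele count in [{lo}, {hi}] for {n_founders} founders"
        )

    alleles = np.zeros((n_founders, n_snps), dtype=np.int8)
    counts = rng.integers(k_min, k_max + 1, size=n_snps)
    for j in range(n_snps):
        carriers = rng.choice(n_founders, size=counts[j], replace=False)
        alleles[carriers, j] = 1

    # SNPs spread over chromosomes with strictly increasing unique positions
    per_chrom = np.full(n_chrom, n_snps // n_chrom)
    per_chrom[: n_snps % n_chrom] += 1
    chrom = np.repeat(np.arange(1, n_chrom + 1), per_chrom)
    pos = np.empty(n_snps, dtype=np.int64)
    start = 0
    for c in range(n_chrom):
        m = per_chrom[c]
        p = np.sort(rng.choice(np.arange(1, chrom_length + 1), size=m, replace=False))
        pos[start : start + m] = p
        start += m

    return FounderHaplotypes(alleles=alleles, chrom=chrom, pos=pos, maf_range=(lo, hi))


def _mosaic(rng, hap_a: np.ndarray, hap_b: np.ndarray, pos: np.ndarray,
            chrom_len: int, crossovers: float) -> np.ndarray:
    """One meiotic gamete: alternate between two parental haplotypes at
    Poisson(crossovers) uniformly placed breakpoints."""
    n_x = rng.poisson(crossovers)
    current = rng.integers(2)
    if n_x == 0:
        return (hap_a if current == 0 else hap_b).copy()
    breaks = np.sort(rng.uniform(0, chrom_len, size=n_x))
    # segment index for each SNP, parity decides the source haplotype
    seg = np.searchsorted(breaks, pos)
    use_b = (seg + current) % 2 == 1
    out = hap_a.copy()
    out[use_b] = hap_b[use_b]
    return out


def simulate_rils(
    founders: FounderHaplotypes,
    n_rils: int = 616,
    crossovers_per_chrom: float = 1.0,
    selfing_generations: int = 6,
    seed: int = 0,
) -> GenotypeMatrix:
    """Breed RILs as founder mosaics with residual heterozygosity.

    Each RIL starts as a synthetic hybrid whose two chromosome copies are
    independent founder mosaics (standing in for the funnel cross), then
    undergoes ``selfing_generations`` rounds of selfing with recombination.
    Per-locus expected heterozygosity halves each selfing generation.
    """
    if n_rils < 1:
        raise ValueError("n_rils must be >= 1")
    if selfing_generations < 0:
        raise ValueError("selfing_generations must be >= 0")
    rng = np.random.default_rng(seed)

    chroms = np.unique(founders.chrom)
    dosages = np.empty((n_rils, founders.n_snps), dtype=np.int8)
    for c in chroms:
        idx = np.flatnonzero(founders.chrom == c)
        pos = founders.pos[idx]
        chrom_len = int(pos.max()) + 1
        F = founders.alleles[:, idx]
        for i in range(n_rils):
            # funnel stand-in: two independent founder mosaics
            h = []
            for _ in range(2):
                n_x = rng.poisson(crossovers_per_chrom)
                breaks = np.sort(rng.uniform(0, chrom_len, size=n_x))
                seg = np.searchsorted(breaks, pos)
                origins = rng.integers(founders.n_founders, size=n_x + 1)
                h.append(F[origins[seg], np.arange(len(idx))])
            h1, h2 = h
            for _ in range(selfing_generations):
                g1 = _mosaic(rng, h1, h2, pos, chrom_len, crossovers_per_chrom)
                g2 = _mosaic(rng, h1, h2, pos, chrom_len, crossovers_per_chrom)
                h1, h2 = g1, g2
            dosages[i, idx] = h1 + h2

    samples = [f"RIL{i + 1:04d}" for i in range(n_rils)]
    return GenotypeMatrix(
        dosages=dosages, samples=samples, chrom=founders.chrom.copy(),
        pos=founders.pos.copy(),
    )


def base_template(wavelengths: np.ndarray = WAVELENGTH_GRID) -> np.ndarray:
    """Analytic leaf-like reflectance template on the nm grid.

    Logistic red-edge rise (700-750 nm) up to a NIR plateau, Gaussian
    absorption wells for chlorophyll (450, 680 nm) and water (1450, 1940 nm),
    and a gentle SWIR decline.  Not a radiative-transfer model; it only has
    to give spectra the right large-scale shape and correlation structure.
    """
    wl = np.asarray(wavelengths, dtype=float)
    r = 0.08 + 0.40 / (1.0 + np.exp(-(wl - 720.0) / 12.0))
    r -= 0.04 * np.exp(-0.5 * ((wl - 450.0) / 35.0) ** 2)
    r -= 0.05 * np.exp(-0.5 * ((wl - 680.0) / 25.0) ** 2)
    r += 0.035 * np.exp(-0.5 * ((wl - 550.0) / 30.0) ** 2)
    r -= 0.18 * np.exp(-0.5 * ((wl - 1450.0) / 55.0) ** 2)
    r -= 0.26 * np.exp(-0.5 * ((wl - 1940.0) / 75.0) ** 2)
    r -= 0.10 / (1.0 + np.exp(-(wl - 1300.0) / 150.0))
    return np.clip(r, 0.02, None)


def _latent_profiles(wl: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "pigment": -np.exp(-0.5 * ((wl - 550.0) / 60.0) ** 2)
        - np.exp(-0.5 * ((wl - 680.0) / 30.0) ** 2),
        "structure": 1.0 / (1.0 + np.exp(-(wl - 730.0) / 15.0))
        * np.exp(-0.5 * ((wl - 1000.0) / 350.0) ** 2),
        "water": -np.exp(-0.5 * ((wl - 1450.0) / 60.0) ** 2)
        - np.exp(-0.5 * ((wl - 1940.0) / 80.0) ** 2),
        "dry_matter": np.exp(-0.5 * ((wl - 2100.0) / 200.0) ** 2),
    }


def default_noise_profile(wavelengths: np.ndarray = WAVELENGTH_GRID,
                          base_sd: float = 0.003) -> np.ndarray:
    """Wavelength-dependent noise SD: elevated at the blue end and in the
    strong water-absorption SWIR bands, mimicking detector signal-to-noise."""
    wl = np.asarray(wavelengths, dtype=float)
    sd = np.full_like(wl, base_sd)
    sd += base_sd * 2.0 * np.exp(-(wl - 400.0) / 80.0)
    sd += base_sd * 1.5 * np.exp(-0.5 * ((wl - 1940.0) / 100.0) ** 2)
    sd += base_sd * np.exp(-0.5 * ((wl - 2450.0) / 80.0) ** 2)
    return sd


def simulate_spectra(
    genotypes: GenotypeMatrix,
    effects: EffectSpec | None = None,
    env: EnvironmentalDesign | None = None,
    noise_sd: np.ndarray | float = 0.003,
    phytometer_fraction: float = 0.25,
    seed: int = 0,
    wavelengths: np.ndarray = WAVELENGTH_GRID,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Simulate leaf spectra plus metadata for each genotyped sample.

    Returns ``(spectra, metadata, truth)`` where spectra is a samples x
    wavelengths DataFrame (integer nm columns), metadata carries the factors
    LN, REP, BA, DT, CT, MO and a ``phytometer`` flag, and truth records the
    planted causal SNPs, realized per-term variance fractions (averaged over
    wavelengths) and the noise profile.
    """
    effects = effects or EffectSpec()
    env = env or EnvironmentalDesign()
    effects.validate()
    rng = np.random.default_rng(seed)
    wl = np.asarray(wavelengths)
    n = genotypes.n_samples
    p = len(wl)

    if np.isscalar(noise_sd):
        noise_sd = np.full(p, float(noise_sd))
    noise_sd = np.asarray(noise_sd, dtype=float)
    if noise_sd.shape != (p,):
        raise ValueError("noise_sd profile length must match wavelength grid")

    # metadata: factors assigned round-robin/randomly; one patch per 4 plants
    n_patch = max(env.n_patch, 1)
    meta = pd.DataFrame(
        {
            "LN": rng.integers(1, env.n_ln + 1, size=n),
            "REP": np.repeat([1, 2], [n - n // 2, n // 2])[:n]
            if env.n_rep == 2
            else rng.integers(1, env.n_rep + 1, size=n),
            "BA": rng.integers(1, n_patch + 1, size=n),
            "DT": rng.integers(1, env.n_dt + 1, size=n),
            "CT": rng.integers(1, env.n_ct + 1, size=n),
            "MO": rng.integers(1, env.n_mo + 1, size=n),
        },
        index=pd.Index(genotypes.samples, name="sample"),
    )
    phyto = rng.random(n) < phytometer_fraction
    meta["phytometer"] = phyto

    base = base_template(wl)
    genetic = np.zeros((n, p))
    band_mask = {}
    for c in effects.causal_snps:
        m = (wl >= c.band_lo) & (wl <= c.band_hi)
        band_mask[c.snp_index] = m
        genetic[:, m] += np.outer(genotypes.dosages[:, c.snp_index].astype(float), np.full(m.sum(), c.effect))
    # latent leaf-feature factors (also genetic-independent sample variation)
    profiles = _latent_profiles(wl.astype(float))
    profiles["amplitude"] = base_template(wl)
    for name, sd in (
        ("pigment", effects.pigment_sd),
        ("structure", effects.structure_sd),
        ("water", effects.water_sd),
        ("dry_matter", effects.dry_matter_sd),
        ("amplitude", effects.amplitude_sd),
    ):
        if sd > 0:
            genetic += np.outer(rng.normal(0.0, sd, size=n), profiles[name])
    genetic[phyto, :] = 0.0  # phytometers are the invariant tester genotype

    # environmental level effects, one draw per level (flat across wavelengths)
    def level_effects(levels: pd.Series, sd: float) -> np.ndarray:
        if sd <= 0:
            return np.zeros(n)
        uniq, inv = np.unique(levels, return_inverse=True)
        draws = rng.normal(0.0, sd, size=len(uniq))
        return draws[inv]

    terms = {
        "LN": level_effects(meta["LN"], env.ln_sd),
        "REP": level_effects(meta["REP"], env.rep_sd),
        "BA": level_effects(meta["BA"], env.patch_sd),
        "LN:REP": level_effects(
            meta["LN"].astype(str) + ":" + meta["REP"].astype(str), env.ln_rep_sd
        ),
        "LN:BA": level_effects(
            meta["LN"].astype(str) + ":" + meta["BA"].astype(str), env.ln_patch_sd
        ),
        "DT": level_effects(meta["DT"], env.dt_sd),
        "CT": level_effects(meta["CT"], env.ct_sd),
        "DT:CT": level_effects(
            meta["DT"].astype(str) + ":" + meta["CT"].astype(str), env.dt_ct_sd
        ),
        "MO": level_effects(meta["MO"], env.mo_sd),
    }
    environmental = sum(terms.values())
    noise = rng.normal(0.0, 1.0, size=(n, p)) * noise_sd[None, :]

    values = base[None, :] + genetic + environmental[:, None] + noise

    # realized per-component variances; fractions against their sum so the
    # environmental terms stay in [0, 1] and sum to < 1
    env_var = {name: float(np.var(eff, ddof=1)) if np.var(eff) > 0 else 0.0
               for name, eff in terms.items()}
    genetic_var = float(genetic.var(axis=0, ddof=1).mean())
    noise_var = float(noise.var(axis=0, ddof=1).mean())
    total_comp = sum(env_var.values()) + genetic_var + noise_var
    fractions: dict[str, float] = {}
    genetic_fraction = noise_fraction = 0.0
    if total_comp > 0:
        fractions = {k: v / total_comp for k, v in env_var.items()}
        genetic_fraction = genetic_var / total_comp
        noise_fraction = noise_var / total_comp

    spectra = pd.DataFrame(values, index=meta.index.copy(), columns=wl)
    truth = TruthRecord(
        causal_snps=list(effects.causal_snps),
        variance_fractions=fractions,
        noise_sd=noise_sd,
        phytometer=phyto,
        seed=seed,
        genetic_fraction=genetic_fraction,
        noise_fraction=noise_fraction,
    )
    truth.validate()
    return spectra, meta, truth


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write dosages as an unphased GT-only VCF (REF=A, ALT=T placeholders)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in np.unique(genotypes.chrom):
            fh.write(f"##contig=<ID=chr{c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j in range(genotypes.n_snps):
            row = [
                f"chr{genotypes.chrom[j]}",
                str(genotypes.pos[j]),
                f"chr{genotypes.chrom[j]}_{genotypes.pos[j]}",
                "A",
                "T",
                ".",
                "PASS",
                ".",
                "GT",
            ] + [gt_map[int(d)] for d in genotypes.dosages[:, j]]
            fh.write("\t".join(row) + "\n")


def write_truth(truth: TruthRecord, path) -> None:
    """Serialize a TruthRecord as a structured plain-text file."""
    with open(path, "w") as fh:
        fh.write(f"seed\t{truth.seed}\n")
        for c in truth.causal_snps:
            fh.write(f"causal\t{c.snp_index}\t{c.band_lo}\t{c.band_hi}\t{c.effect}\n")
        for k, v in truth.variance_fractions.items():
            fh.write(f"variance_fraction\t{k}\t{v}\n")
        fh.write("noise_sd\t" + ",".join(f"{s:.6g}" for s in truth.noise_sd) + "\n")
        fh.write("phytometer\t" + ",".join("1" if f else "0" for f in truth.phytometer) + "\n")
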