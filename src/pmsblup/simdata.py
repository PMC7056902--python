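"""Synthetic F2-cross generator for testing the prediction pipeline.

The generator emulates the data structure of a two-line broiler F2 design:
two divergent founder lines (a selected sire line and an indigenous dam
line), 20 F0 founders (6 males + 14 females), F1 matings, and 395 F2 birds
in 8 half-sib families sharing an F1 sire.  Genotypes arise by gene
dropping founder haplotypes through two meioses with Haldane (no
interference) recombination over 28 autosomes; phenotypes are built from
additive QTL effects plus sex, batch and residual terms, calibrated to a
12-week body-weight-like trait (mean 2034, SD 360) at a target
heritability.

Default sizes mirror the study design this package targets; panel size,
QTL count, heritability, and missingness are free parameters.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeMatrix

#: per-genotype missing rates typical of a 10X reduced-representation
#: sequencing panel and of a SNP chip (per-individual missing-call means of
#: roughly 6,200/121,000 and 230/46,700 markers respectively)
SEQ_MISSING_RATE = 0.051
CHIP_MISSING_RATE = 0.005


@dataclass
class SimConfig:
    """Parameters of the F2-cross simulation.

    ``sex_effect`` is the male-minus-female difference in trait units
    (applied as +/- half to each sex); ``batch_effects`` are per-batch
    deviations in trait units.  ``divergence`` is the Beta concentration of
    line allele frequencies around each marker's base frequency — smaller
    values give more divergent founder lines.
    """

    n_f0_males: int = 6
    n_f0_females: int = 14
    n_families: int = 8
    n_f2: int = 395
    n_chromosomes: int = 28
    chromosome_length: float = 1.0  # Morgans
    n_markers: int = 46_690
    founder_maf_range: tuple = (0.05, 0.5)
    divergence: float = 10.0
    n_qtl: int = 100
    qtl_in_panel: bool = True
    h2_target: float = 0.703
    trait_mean: float = 2034.0
    trait_sd: float = 360.0
    sex_effect: float = 300.0
    batch_effects: tuple = (-50.0, -30.0, -10.0, 10.0, 30.0, 50.0)
    n_batches: int = 6
    prop_male: float = 212 / 395
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_f0_males", "n_f0_females", "n_families", "n_f2",
                     "n_chromosomes", "n_markers", "n_batches"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if len(self.batch_effects) != self.n_batches:
            raise ValueError("batch_effects length must equal n_batches")


@dataclass
class SimOutput:
    """Genotypes, phenotypes and the underlying truth of one simulation."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    pedigree: pd.DataFrame
    true_breeding_values: pd.Series
    qtl: pd.DataFrame  # marker_id, chromosome, position, effect
    realized_h2: float
    sigma_e2: float
    config: SimConfig


# ---------------------------------------------------------------------------
# Genotypes


def _marker_map(cfg: SimConfig, rng) -> pd.DataFrame:
    """Assign markers to chromosomes with uniform genetic positions."""
    chrom = np.sort(rng.integers(1, cfg.n_chromosomes + 1, cfg.n_markers))
    morgans = rng.uniform(0.0, cfg.chromosome_length, cfg.n_markers)
    order = np.lexsort((morgans, chrom))
    chrom, morgans = chrom[order], morgans[order]
    return pd.DataFrame(
        {
            "marker_id": [f"snp{i + 1}" for i in range(cfg.n_markers)],
            "chromosome": chrom.astype(str),
            "position": np.maximum((morgans * 1e6).astype(np.int64), 1),
            "allele1": "A",
            "allele2": "B",
            "morgans": morgans,
        }
    )


def _recomb_fractions(markers: pd.DataFrame) -> np.ndarray:
    """Per-interval recombination fraction; 0.5 across chromosome boundaries.

    Haldane map: r = (1 - exp(-2 d)) / 2 for genetic distance d in Morgans.
    Element 0 is 0.5 so the starting haplotype of each meiosis is uniform.
    """
    d = np.diff(markers["morgans"].to_numpy(), prepend=np.nan)
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    new_chrom = markers["chromosome"].ne(markers["chromosome"].shift()).to_numpy()
    r[new_chrom] = 0.5
    return r


def _meiosis(h0: np.ndarray, h1: np.ndarray, r: np.ndarray, rng) -> np.ndarray:
    """One gamete per row: recombine parental haplotypes h0/h1 (shape g x m)."""
    switch = rng.random(h0.shape) < r
    use_h1 = np.cumsum(switch, axis=1) % 2 == 1
    return np.where(use_h1, h1, h0)


def simulate_genotypes(cfg: SimConfig, rng=None) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Gene-drop an F2 cross; returns the F2 genotypes and the pedigree.

    Founder haplotypes are drawn per line from Beta-perturbed allele
    frequencies around a shared base frequency, mimicking two divergent
    lines.  Each half-sib family shares one F1 sire; dams are F1 females of
    the same family group.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    markers = _marker_map(cfg, rng)
    r = _recomb_fractions(markers)
    m = cfg.n_markers

    base = rng.uniform(*cfg.founder_maf_range, m)
    c = cfg.divergence
    p_line = [rng.beta(base * c, (1.0 - base) * c), rng.beta(base * c, (1.0 - base) * c)]
    markers["freq_line1"] = p_line[0]  # realized line frequencies, kept as
    markers["freq_line2"] = p_line[1]  # truth metadata for diagnostics

    # F0: males from line 0, females from line 1
    def draw_haplotypes(n, p):
        return (rng.random((n, m)) < p).astype(np.int8), (rng.random((n, m)) < p).astype(np.int8)

    f0m_h0, f0m_h1 = draw_haplotypes(cfg.n_f0_males, p_line[0])
    f0f_h0, f0f_h1 = draw_haplotypes(cfg.n_f0_females, p_line[1])

    # F1: one sire + a dam group per family, each from a random F0 pair
    dams_per_family = max(2, cfg.n_f0_females // cfg.n_families + 1)
    n_f1 = cfg.n_families * (1 + dams_per_family)
    sire_idx = rng.integers(0, cfg.n_f0_males, n_f1)
    dam_idx = rng.integers(0, cfg.n_f0_females, n_f1)
    f1_h0 = _meiosis(f0m_h0[sire_idx], f0m_h1[sire_idx], r, rng)
    f1_h1 = _meiosis(f0f_h0[dam_idx], f0f_h1[dam_idx], r, rng)
    f1_sires = np.arange(cfg.n_families)  # first one per family is the sire
    f1_dams = np.arange(cfg.n_families, n_f1).reshape(cfg.n_families, dams_per_family)

    # F2: family sizes as even as possible
    fam = np.repeat(np.arange(cfg.n_families), int(np.ceil(cfg.n_f2 / cfg.n_families)))[
        : cfg.n_f2
    ]
    dam_of = np.array([rng.choice(f1_dams[f]) for f in fam])
    sire_of = f1_sires[fam]
    pat = _meiosis(f1_h0[sire_of], f1_h1[sire_of], r, rng)
    mat = _meiosis(f1_h0[dam_of], f1_h1[dam_of], r, rng)
    dosages = (pat + mat).astype(np.int16)

    ids = [f"F2_{i + 1:04d}" for i in range(cfg.n_f2)]
    sex = np.where(rng.random(cfg.n_f2) < cfg.prop_male, "M", "F")
    pedigree = pd.DataFrame(
        {
            "id": ids,
            "family": fam + 1,
            "sire": [f"F1_{s + 1}" for s in sire_of],
            "dam": [f"F1_{d + 1}" for d in dam_of],
            "sex": sex,
        }
    )
    g = GenotypeMatrix(ids, markers.drop(columns="morgans"), dosages)
    return g, pedigree


# ---------------------------------------------------------------------------
# Phenotypes


def simulate_phenotypes(
    g: GenotypeMatrix, cfg: SimConfig, pedigree: pd.DataFrame = None, rng=None
):
    """Additive QTL phenotypes with sex and batch fixed effects.

    QTL markers are sampled from the panel; raw N(0,1) effects are rescaled
    so the realized genetic variance is h2_target * trait_sd^2, and the
    residual variance is set so var(TBV)/(var(TBV)+sigma_e^2) equals
    h2_target exactly in the realized sample.  Batches are assigned
    round-robin.  Returns (phenotypes, truth dict).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    n = g.n_individuals
    qtl_idx = np.sort(rng.choice(g.n_markers, cfg.n_qtl, replace=False))
    effects = rng.normal(0.0, 1.0, cfg.n_qtl)
    dos = g.dosages[:, qtl_idx].astype(float)
    if (dos == MISSING).any():
        raise ValueError("simulate phenotypes before applying missingness")
    tbv = dos @ effects
    v = tbv.var()
    if cfg.h2_target > 0 and v <= 0:
        raise ValueError("zero TBV variance with positive h2_target; "
                         "QTLs are monomorphic in this sample")
    if cfg.h2_target == 0 or v == 0:
        tbv = np.zeros(n)
        effects = np.zeros(cfg.n_qtl)
        sigma_e2 = cfg.trait_sd**2
        realized_h2 = 0.0
    else:
        scale = np.sqrt(cfg.h2_target * cfg.trait_sd**2 / v)
        tbv *= scale
        effects *= scale
        vg = tbv.var()
        sigma_e2 = vg * (1.0 - cfg.h2_target) / cfg.h2_target if cfg.h2_target < 1 else 0.0
        realized_h2 = vg / (vg + sigma_e2) if vg + sigma_e2 > 0 else 0.0

    if pedigree is not None:
        sex = pedigree.set_index("id").loc[g.individual_ids, "sex"].to_numpy()
    else:
        sex = np.where(rng.random(n) < cfg.prop_male, "M", "F")
    batch = np.arange(n) % cfg.n_batches
    e = rng.normal(0.0, np.sqrt(sigma_e2), n)
    y = (
        cfg.trait_mean
        + np.where(sex == "M", 0.5, -0.5) * cfg.sex_effect
        + np.asarray(cfg.batch_effects)[batch]
        + (tbv - tbv.mean())
        + e
    )
    phenotypes = pd.DataFrame(
        {
            "id": g.individual_ids,
            "trait": y,
            "sex": sex,
            "batch": [f"B{b + 1}" for b in batch],
        }
    )
    truth = {
        "tbv": pd.Series(tbv, index=g.individual_ids, name="tbv"),
        "qtl": pd.concat(
            [
                g.markers.iloc[qtl_idx][["marker_id", "chromosome", "position"]].reset_index(
                    drop=True
                ),
                pd.Series(effects, name="effect"),
            ],
            axis=1,
        ),
        "realized_h2": float(realized_h2),
        "sigma_e2": float(sigma_e2),
    }
    return phenotypes, truth


def apply_missingness(g: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each genotype missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return g
    rng = np.random.default_rng(seed)
    mask = rng.random(g.dosages.shape) < rate
    dos = np.where(mask, MISSING, g.dosages)
    return GenotypeMatrix(g.individual_ids, g.markers.copy(), dos)


def simulate(cfg: SimConfig) -> SimOutput:
    """Full simulation: genotypes, phenotypes, truth, then missingness.

    QTL markers can be excluded from the released panel with
    ``qtl_in_panel=False`` (prediction must then rely on linked markers).
    """
    rng = np.random.default_rng(cfg.seed)
    g, ped = simulate_genotypes(cfg, rng)
    phen, truth = simulate_phenotypes(g, cfg, ped, rng)
    panel = g
    if not cfg.qtl_in_panel:
        keep = ~np.isin(g.marker_ids, truth["qtl"]["marker_id"].to_numpy())
        panel = g.subset_markers(keep)
    if cfg.missing_rate > 0:
        panel = apply_missingness(
            panel, cfg.missing_rate, int(rng.integers(0, 2**31 - 1))
        )
    return SimOutput(
        genotypes=panel,
        phenotypes=phen,
        pedigree=ped,
        true_breeding_values=truth["tbv"],
        qtl=truth["qtl"],
        realized_h2=truth["realized_h2"],
        sigma_e2=truth["sigma_e2"],
        config=cfg,
    )


def write_sim(out: SimOutput, directory) -> None:
    """Emit VCF + phenotype CSV + truth TSV + the config as YAML."""
    import os

    import yaml

    from .data import write_vcf

    os.makedirs(directory, exist_ok=True)
    write_vcf(out.genotypes, os.path.join(directory, "genotypes.vcf"))
    out.phenotypes.to_csv(os.path.join(directory, "phenotypes.csv"), index=False)
    out.pedigree.to_csv(os.path.join(directory, "pedigree.csv"), index=False)
    truth = pd.DataFrame(
        {"id": out.true_breeding_values.index, "tbv": out.true_breeding_values.to_numpy()}
    )
    truth.to_csv(os.path.join(directory, "tbv.tsv"), sep="\t", index=False)
    out.qtl.to_csv(os.path.join(directory, "qtl.tsv"), sep="\t", index=False)
    cfg = asdict(out.config)
    cfg["founder_maf_range"] = list(cfg["founder_maf_range"])
    cfg["batch_effects"] = list(cfg["batch_effects"])
    cfg["realized_h2"] = out.realized_h2
    with open(os.path.join(directory, "sim_config.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
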