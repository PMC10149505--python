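"""Synthetic two-group cohort with planted ground truth.

Generates every input layer the pipeline consumes — TMT-style proteome
intensities with batch structure and internal reference channels, two-run
LFQ surfaceome with intensity-dependent missingness, negative-binomial
transcriptome counts (also reported as TPM), viability screen plates,
variant tables and survival times — together with a
:class:`CohortTruth` ledger recording every planted effect so that each
downstream estimator can be tested for recovery.

The default panel mirrors the study design this package targets: 10 benign
(BPH) + 25 tumor models, four TMT batches each carrying one pooled
internal-reference channel, 33 drugs at 7 ten-fold dilutions in triplicate
with DMSO and total-kill controls, and 29 models entering the screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    OmicsMatrix,
    PlateRecord,
    SampleAnnotation,
    SurvivalRecord,
    VariantRecord,
)
from .dose_response import loglogistic3

VARIANT_CLASSES = (
    "missense_variant",
    "stop_gained",
    "frameshift_variant",
    "inframe_deletion",
    "splice_site_variant",
    "synonymous_variant",
)
CLASS_TO_TYPE = {
    "missense_variant": "SNP",
    "stop_gained": "SNP",
    "synonymous_variant": "SNP",
    "splice_site_variant": "SNP",
    "frameshift_variant": "INS",
    "inframe_deletion": "DEL",
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_bph: int = 10
    n_tumor: int = 25
    n_proteins: int = 2000
    n_surface: int = 600
    n_genes: int = 2000
    n_batches: int = 4
    n_drugs: int = 33
    n_doses: int = 7
    dilution_factor: float = 10.0
    replicates: int = 3
    top_dose_uM: float = 10.0
    screen_n_bph: int = 10
    screen_n_tumor: int = 19  # 29 models enter the screen

    # planted effects
    differential_fraction: float = 0.05
    differential_log2fc: float = 1.0
    n_selective_drugs: int = 5
    selective_log10e_shift: float = 1.0  # tumor inflection shifted down
    n_couplings: int = 5
    coupling_strength: float = 0.8  # in [0, 1]
    n_top_mutated_genes: int = 4
    survival_hazard_ratio: float = 2.0

    # noise / nuisance structure
    protein_noise_sd: float = 0.5  # log2
    surface_noise_sd: float = 0.6  # log2
    batch_sd: float = 0.15  # log2, per protein x batch
    loading_sd: float = 0.25  # log2, per sample
    reference_noise_sd: float = 0.1  # log2, reference channel repeatability
    rna_noise_sd: float = 1.5  # log2 biological noise on transcript means
    rna_dispersion: float = 0.1  # NB dispersion alpha
    rna_mean_counts: float = 200.0
    mrna_protein_rho: float = 0.3  # target per-gene mRNA-protein Spearman
    viability_noise_cv: float = 0.05
    curve_log10e_sd: float = 0.4  # cell-to-cell spread of log10 inflection
    missing_mid_log2: float = 21.0  # logistic MNAR midpoint (surfaceome)
    missing_scale_log2: float = 1.2
    mean_variants_tumor: float = 50.0
    mean_variants_bph: float = 6.0
    n_dmso_wells: int = 6
    n_positive_wells: int = 3
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_bph": self.n_bph,
            "n_tumor": self.n_tumor,
            "n_proteins": self.n_proteins,
            "n_surface": self.n_surface,
            "n_genes": self.n_genes,
            "n_batches": self.n_batches,
            "n_drugs": self.n_drugs,
            "n_doses": self.n_doses,
            "replicates": self.replicates,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if not (0 <= self.differential_fraction <= 1):
            raise ValueError("differential_fraction must be in [0, 1]")
        if not (0 <= self.coupling_strength <= 1):
            raise ValueError("coupling_strength must be in [0, 1]")
        if self.n_surface > self.n_proteins:
            raise ValueError("n_surface cannot exceed n_proteins")
        if self.n_proteins > self.n_genes:
            raise ValueError("n_proteins cannot exceed n_genes (shared namespace)")
        if self.screen_n_bph > self.n_bph or self.screen_n_tumor > self.n_tumor:
            raise ValueError("screened cells cannot exceed cohort size")


@dataclass
class CohortTruth:
    """Ground-truth ledger of every planted effect."""

    # feature -> {layer: true log2 fold change (tumor vs BPH)}
    differential_features: dict[str, dict[str, float]]
    # drug -> true group shift in 7-AA (tumor minus BPH, noiseless curves)
    selective_drugs: dict[str, float]
    # (protein, drug) -> (sign, strength in [0, 1])
    protein_drug_couplings: dict[tuple[str, str], tuple[int, float]]
    # (cell, drug) -> (b, c, e)
    true_curves: dict[tuple[str, str], tuple[float, float, float]]
    survival_hazard_ratio: float
    top_mutated_genes: list[str] = field(default_factory=list)
    doses_uM: list[float] = field(default_factory=list)
    screen_cells: list[str] = field(default_factory=list)

    def validate_against(self, feature_ids: set[str], drugs: set[str]) -> None:
        for feature in self.differential_features:
            if feature not in feature_ids:
                raise ValueError(f"planted feature {feature!r} missing from data")
        for drug in self.selective_drugs:
            if drug not in drugs:
                raise ValueError(f"planted selective drug {drug!r} missing")
        for (_, drug), (sign, strength) in self.protein_drug_couplings.items():
            if not (0 <= strength <= 1):
                raise ValueError("coupling strength must be in [0, 1]")
            if sign not in (-1, 1):
                raise ValueError("coupling sign must be -1 or +1")


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, OmicsMatrix], list[SampleAnnotation], list[VariantRecord], CohortTruth]:
    """Generate the full cohort; deterministic under a fixed config seed.

    Returns ``(matrices, annotations, variants, truth)`` where ``matrices``
    holds raw (un-normalized) layers keyed ``proteome`` / ``surfaceome_run1``
    / ``surfaceome_run2`` / ``transcriptome_counts`` / ``transcriptome`` (TPM).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _gene_names(config.n_genes)
    proteins = genes[: config.n_proteins]
    surface = proteins[: config.n_surface]

    samples = [f"BPH{i + 1:02d}" for i in range(config.n_bph)] + [
        f"T{i + 1:02d}" for i in range(config.n_tumor)
    ]
    groups = ["BPH"] * config.n_bph + ["tumor"] * config.n_tumor
    n_samples = len(samples)
    batches = [f"B{(i % config.n_batches) + 1}" for i in range(n_samples)]

    annotations = [
        SampleAnnotation(
            sample_id=s,
            group=g,
            batch=b,
            gleason=int(rng.integers(6, 11)) if g == "tumor" else None,
        )
        for s, g, b in zip(samples, groups, batches)
    ]
    ref_ids = []
    for k in range(config.n_batches):
        rid = f"REF_B{k + 1}"
        ref_ids.append(rid)
        annotations.append(
            SampleAnnotation(sample_id=rid, group="tumor", batch=f"B{k + 1}", reference_flag=True)
        )

    tumor_mask = np.array([g == "tumor" for g in groups])

    # ---- planted differential features --------------------------------
    n_diff = int(round(config.differential_fraction * config.n_proteins))
    diff_proteins = (
        [str(p) for p in rng.choice(proteins, size=n_diff, replace=False)] if n_diff else []
    )
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    differential: dict[str, dict[str, float]] = {}
    for feat, sgn in zip(diff_proteins, signs):
        lfc = float(sgn * config.differential_log2fc)
        differential[feat] = {"proteome": lfc, "transcriptome": lfc}
        if feat in set(surface):
            differential[feat]["surfaceome"] = lfc

    def group_effect(layer: str) -> np.ndarray:
        eff = np.zeros((len(proteins), n_samples))
        index = {p: i for i, p in enumerate(proteins)}
        for feat, layers in differential.items():
            if layer in layers:
                eff[index[feat], tumor_mask] = layers[layer]
        return eff

    # ---- proteome: log-normal reporter intensities --------------------
    mu = rng.normal(20.0, 1.5, size=len(proteins))
    batch_eff = rng.normal(0.0, config.batch_sd, size=(len(proteins), config.n_batches))
    loading = rng.normal(0.0, config.loading_sd, size=n_samples)
    batch_idx = np.array([int(b[1:]) - 1 for b in batches])

    signal = (
        mu[:, None]
        + group_effect("proteome")
        + rng.normal(0.0, config.protein_noise_sd, size=(len(proteins), n_samples))
    )
    prot_log2 = signal + batch_eff[:, batch_idx] + loading[None, :]
    prot_linear = np.power(2.0, prot_log2)

    # pooled internal reference: per-feature mean of the sample intensities,
    # re-measured in each batch with that batch's effect (so the sample/ref
    # ratio cancels it) plus channel repeatability noise
    pooled = prot_linear.mean(axis=1)
    ref_cols = {}
    for k, rid in enumerate(ref_ids):
        ref_noise = rng.normal(0.0, config.reference_noise_sd, size=len(proteins))
        ref_cols[rid] = pooled * np.power(2.0, batch_eff[:, k] + ref_noise)
    proteome = pd.DataFrame(prot_linear, index=proteins, columns=samples)
    for rid, col in ref_cols.items():
        proteome[rid] = col

    # ---- surfaceome: two LFQ runs with MNAR missingness ----------------
    prot_index = {p: i for i, p in enumerate(proteins)}
    mu_s = rng.normal(22.0, 2.0, size=len(surface))
    surf_rows = np.array([prot_index[p] for p in surface])
    surf_signal = (
        mu_s[:, None]
        + group_effect("surfaceome")[surf_rows, :]
    )
    runs = {}
    for run in (1, 2):
        log2_run = surf_signal + rng.normal(
            0.0, config.surface_noise_sd, size=(len(surface), n_samples)
        )
        p_missing = 1.0 / (
            1.0 + np.exp((log2_run - config.missing_mid_log2) / config.missing_scale_log2)
        )
        drop = rng.uniform(size=log2_run.shape) < p_missing
        linear = np.power(2.0, log2_run)
        linear[drop] = np.nan
        runs[run] = pd.DataFrame(linear, index=surface, columns=samples)

    # ---- transcriptome: NB counts sharing a latent with the proteome ---
    # per-gene correlation target rho: transcript log-mean = protein signal
    # deviation + independent noise with sd chosen from rho
    rho = config.mrna_protein_rho
    extra_sd = (
        config.protein_noise_sd * np.sqrt(max(1.0 / rho**2 - 1.0, 0.0))
        if rho > 0
        else config.rna_noise_sd
    )
    mu_rna = np.log2(config.rna_mean_counts) + rng.normal(0.0, 1.0, size=config.n_genes)
    rna_log2 = np.tile(mu_rna[:, None], (1, n_samples)).astype(float)
    prot_dev = signal - mu[:, None]  # protein deviation incl. group effect
    rna_log2[: len(proteins)] += prot_dev
    rna_log2 += rng.normal(0.0, extra_sd, size=rna_log2.shape)
    mean_counts = np.power(2.0, rna_log2)
    if config.rna_dispersion > 0:
        shape = 1.0 / config.rna_dispersion
        lam = rng.gamma(shape, mean_counts * config.rna_dispersion)
    else:
        lam = mean_counts
    counts = rng.poisson(lam).astype(float)
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    tpm = counts_df / counts_df.sum(axis=0) * 1e6  # equal effective lengths

    # ---- drug screen truth --------------------------------------------
    drugs = [f"drug{j + 1:02d}" for j in range(config.n_drugs)]
    screen_cells = samples[: config.screen_n_bph] + [
        s for s in samples if s.startswith("T")
    ][: config.screen_n_tumor]
    screen_tumor = {c for c in screen_cells if c.startswith("T")}

    n_sel = min(config.n_selective_drugs, config.n_drugs)
    selective = (
        [str(d) for d in rng.choice(drugs, size=n_sel, replace=False)] if n_sel else []
    )

    n_couple = min(config.n_couplings, config.n_drugs, config.n_proteins)
    couple_proteins = (
        [str(p) for p in rng.choice(proteins, size=n_couple, replace=False)]
        if n_couple
        else []
    )
    nonselective = [d for d in drugs if d not in set(selective)]
    pool = nonselective if len(nonselective) >= n_couple else drugs
    couple_drugs = (
        [str(d) for d in rng.choice(pool, size=n_couple, replace=False)] if n_couple else []
    )
    couplings: dict[tuple[str, str], tuple[int, float]] = {}
    for p, d in zip(couple_proteins, couple_drugs):
        sign = int(rng.choice([-1, 1]))
        couplings[(p, d)] = (sign, config.coupling_strength)
    coupled_drug_of: dict[str, tuple[str, int, float]] = {
        d: (p, s, st) for (p, d), (s, st) in couplings.items()
    }

    # standardized log2 protein abundance per screened cell (noise-free part)
    sample_index = {s: i for i, s in enumerate(samples)}
    z_protein: dict[str, np.ndarray] = {}
    for (p, d) in couplings:
        row = signal[prot_index[p], :]
        z = (row - row.mean()) / row.std()
        z_protein[p] = z

    log10_top = np.log10(config.top_dose_uM)
    base_log10e = rng.normal(log10_top - 2.0, 1.0, size=config.n_drugs)
    true_curves: dict[tuple[str, str], tuple[float, float, float]] = {}
    for j, drug in enumerate(drugs):
        b_drug = float(rng.uniform(0.7, 2.0))
        c_drug = float(rng.uniform(0.0, 0.25))
        for cell in screen_cells:
            log10e = base_log10e[j] + rng.normal(0.0, config.curve_log10e_sd)
            if drug in set(selective) and cell in screen_tumor:
                log10e -= config.selective_log10e_shift
            if drug in coupled_drug_of:
                p, sgn, strength = coupled_drug_of[drug]
                log10e += sgn * strength * 1.5 * z_protein[p][sample_index[cell]]
            true_curves[(cell, drug)] = (b_drug, c_drug, float(10.0**log10e))

    doses = [config.top_dose_uM / config.dilution_factor**i for i in range(config.n_doses)]
    doses = sorted(doses)

    # noiseless 7-AA shift implied by the planted curves
    def seven_aa_of(cell: str, drug: str) -> float:
        b, c, e = true_curves[(cell, drug)]
        v = np.clip(loglogistic3(np.array(doses), b, c, e), 0.0, 1.0)
        return config.n_doses - float(np.sum(1.0 - v))

    selective_shift = {}
    tumor_cells = [c for c in screen_cells if c in screen_tumor]
    bph_cells = [c for c in screen_cells if c not in screen_tumor]
    for drug in selective:
        if not tumor_cells or not bph_cells:
            selective_shift[drug] = float("nan")
            continue
        t = np.mean([seven_aa_of(c, drug) for c in tumor_cells])
        bph = np.mean([seven_aa_of(c, drug) for c in bph_cells])
        selective_shift[drug] = float(t - bph)

    # ---- variants ------------------------------------------------------
    top_gene_pool = genes[config.n_proteins :] or genes
    top_genes = [
        str(g) for g in rng.choice(top_gene_pool, size=config.n_top_mutated_genes, replace=False)
    ]
    variants: list[VariantRecord] = []
    class_p = np.array([0.55, 0.1, 0.1, 0.08, 0.07, 0.1])
    for s, g in zip(samples, groups):
        mean = config.mean_variants_tumor if g == "tumor" else config.mean_variants_bph
        n_var = int(rng.poisson(mean))
        hit_genes = [str(g) for g in rng.choice(genes, size=n_var, replace=True)]
        if g == "tumor":
            for tg in top_genes:
                if rng.uniform() < 0.6:
                    hit_genes.append(tg)
        for gene in hit_genes:
            cls = str(rng.choice(VARIANT_CLASSES, p=class_p))
            variants.append(
                VariantRecord(
                    sample_id=s,
                    gene=gene,
                    variant_classification=cls,
                    variant_type=CLASS_TO_TYPE[cls],
                )
            )

    truth = CohortTruth(
        differential_features=differential,
        selective_drugs=selective_shift,
        protein_drug_couplings=couplings,
        true_curves=true_curves,
        survival_hazard_ratio=config.survival_hazard_ratio,
        top_mutated_genes=top_genes,
        doses_uM=doses,
        screen_cells=screen_cells,
    )
    truth.validate_against(set(genes), set(drugs))

    matrices = {
        "proteome": OmicsMatrix(proteome, "proteome"),
        "surfaceome_run1": OmicsMatrix(runs[1], "surfaceome"),
        "surfaceome_run2": OmicsMatrix(runs[2], "surfaceome"),
        "transcriptome_counts": OmicsMatrix(counts_df, "transcriptome"),
        "transcriptome": OmicsMatrix(tpm, "transcriptome"),
    }
    return matrices, annotations, variants, truth


def simulate_plates(truth: CohortTruth, config: SimulationConfig) -> list[PlateRecord]:
    """Viability plates from the planted curves: triplicate treatments at
    each dose, DMSO controls at baseline and near-zero total-kill wells."""
    config.validate()
    if not truth.true_curves:
        raise ValueError("truth.true_curves is empty")
    rng = np.random.default_rng(config.seed + 1)
    doses = truth.doses_uM or sorted(
        config.top_dose_uM / config.dilution_factor**i for i in range(config.n_doses)
    )
    cells = truth.screen_cells or sorted({c for c, _ in truth.true_curves})
    drugs = sorted({d for _, d in truth.true_curves})
    for cell in cells:
        for drug in drugs:
            if (cell, drug) not in truth.true_curves:
                raise ValueError(f"no true curve for pair ({cell!r}, {drug!r})")

    records: list[PlateRecord] = []
    for cell in cells:
        baseline = float(1e5 * rng.lognormal(0.0, 0.2))
        for rep in range(1, config.n_dmso_wells + 1):
            noise = 1.0 + rng.normal(0.0, config.viability_noise_cv)
            records.append(
                PlateRecord(cell, "DMSO", 0.0, rep, baseline * max(noise, 0.0), "dmso_control")
            )
        for rep in range(1, config.n_positive_wells + 1):
            records.append(
                PlateRecord(
                    cell,
                    "positive",
                    0.0,
                    rep,
                    baseline * abs(rng.normal(0.005, 0.002)),
                    "positive_control",
                )
            )
        for drug in drugs:
            b, c, e = truth.true_curves[(cell, drug)]
            for dose in doses:
                v = loglogistic3(dose, b, c, e)
                for rep in range(1, config.replicates + 1):
                    noise = 1.0 + rng.normal(0.0, config.viability_noise_cv)
                    records.append(
                        PlateRecord(cell, drug, float(dose), rep, baseline * v * max(noise, 0.0), "treatment")
                    )
    return records


def simulate_survival(
    n_per_group: int, hazard_ratio: float, censor_rate: float, seed: int
) -> list[SurvivalRecord]:
    """Exponential survival for two groups; group 2's hazard is multiplied
    by ``hazard_ratio``; censoring is independent exponential."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    base_hazard = 0.1
    records: list[SurvivalRecord] = []
    for group, hazard in (("group1", base_hazard), ("group2", base_hazard * hazard_ratio)):
        times = rng.exponential(1.0 / hazard, size=n_per_group)
        if censor_rate > 0:
            c_rate = base_hazard * censor_rate / (1.0 - censor_rate)
            censor = rng.exponential(1.0 / c_rate, size=n_per_group)
        else:
            censor = np.full(n_per_group, np.inf)
        observed = np.minimum(times, censor)
        event = times <= censor
        for i, (t, ev) in enumerate(zip(observed, event)):
            records.append(SurvivalRecord(f"{group}_{i + 1:03d}", float(t), bool(ev), group))
    return records
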