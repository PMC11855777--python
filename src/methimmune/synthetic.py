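"""Synthetic study generator.

Emulates the statistical structure the analysis assumes — a purified-immune-cell
reference panel (7 cell types x 6 replicates by default, mirroring typical
sorted-leukocyte 450K panels), bulk tissue mixtures drawn on the simplex with an
unexplained non-immune component, beta-coupled expression, and subtype-dependent
survival — while recording ground truth for every stage so recovery can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_io import BetaMatrix, SampleSheet, ValidationError, write_matrix, write_table

__all__ = [
    "DEFAULT_CELL_TYPES",
    "SyntheticTruth",
    "CohortConfig",
    "SyntheticCohort",
    "generate_reference_panel",
    "mix_samples",
    "generate_mixtures",
    "generate_expression",
    "generate_survival",
    "generate_cohort",
]

DEFAULT_CELL_TYPES = ("CD4", "CD8", "CD56", "CD19", "CD14", "Neu", "Eos")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators.

    ``true_fractions`` are the exact immune fractions used to mix each sample
    (rows sum to <= 1; the remainder is the non-immune mass).
    """

    true_fractions: pd.DataFrame | None = None
    nonimmune_mass: pd.Series | None = None
    marker_assignment: pd.Series | None = None       # gene -> cell type
    marker_direction: pd.Series | None = None        # gene -> hyper | hypo
    planted_subtype: pd.Series | None = None         # sample -> subtype label
    planted_effects: pd.DataFrame | None = None      # subtype x cell-type mean shift
    survival_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_fractions is not None:
            f = self.true_fractions.to_numpy()
            if (f < -1e-12).any():
                raise ValidationError("true fractions must be nonnegative")
            if (f.sum(axis=1) > 1 + 1e-9).any():
                raise ValidationError("true fraction rows must sum to <= 1")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def generate_reference_panel(
    n_cell_types: int = 7,
    n_replicates: int = 6,
    n_genes: int = 2000,
    n_markers_per_type: int = 50,
    marker_delta: float = 0.4,
    replicate_sd: float = 0.02,
    baseline_range: tuple[float, float] = (0.2, 0.8),
    cell_types: Sequence[str] | None = None,
    seed: int | None = None,
) -> tuple[BetaMatrix, SampleSheet, SyntheticTruth]:
    """Simulate a purified-cell methylation reference panel.

    Non-marker genes share one baseline beta across cell types (plus replicate
    noise); each marker gene's owning cell type is shifted by ``marker_delta``
    away from the baseline, hypo-methylated when the baseline is high and
    hyper-methylated when it is low so the planted contrast is not clipped.
    """
    if not 0 < marker_delta < 1:
        raise ValidationError("marker_delta must be in (0, 1)")
    if n_markers_per_type * n_cell_types > n_genes:
        raise ValidationError(
            f"{n_markers_per_type} markers x {n_cell_types} types exceeds {n_genes} genes"
        )
    if replicate_sd < 0:
        raise ValidationError("replicate_sd must be >= 0")
    if cell_types is None:
        cell_types = [DEFAULT_CELL_TYPES[i] if i < len(DEFAULT_CELL_TYPES) else f"CT{i + 1}"
                      for i in range(n_cell_types)]
    cell_types = list(cell_types)
    if len(cell_types) != n_cell_types:
        raise ValidationError("cell_types length must equal n_cell_types")

    rng = _rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    baseline = rng.uniform(*baseline_range, size=n_genes)

    # per-type mean profiles: baseline everywhere, marker contrasts planted
    profiles = np.tile(baseline[:, None], (1, n_cell_types))
    marker_idx = rng.choice(n_genes, size=n_markers_per_type * n_cell_types, replace=False)
    assignment = pd.Series(pd.NA, index=pd.Index(genes, name="gene_id"), dtype="object")
    direction = pd.Series(pd.NA, index=assignment.index, dtype="object")
    for t in range(n_cell_types):
        idx = marker_idx[t * n_markers_per_type:(t + 1) * n_markers_per_type]
        hypo = baseline[idx] > 0.5
        shift = np.where(hypo, -marker_delta, marker_delta)
        profiles[idx, t] = np.clip(baseline[idx] + shift, 0.0, 1.0)
        assignment.iloc[idx] = cell_types[t]
        direction.iloc[idx] = np.where(hypo, "hypo", "hyper")

    columns, rows, cts = [], [], []
    for t, ct in enumerate(cell_types):
        for r in range(n_replicates):
            columns.append(f"{ct}_rep{r + 1}")
            noise = rng.normal(0.0, replicate_sd, size=n_genes) if replicate_sd > 0 else 0.0
            rows.append(np.clip(profiles[:, t] + noise, 0.0, 1.0))
            cts.append(ct)
    values = pd.DataFrame(np.column_stack(rows), index=genes, columns=columns)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": columns,
        "group": "reference",
        "cancer_type": "NA",
        "cell_type": cts,
    }))
    truth = SyntheticTruth(marker_assignment=assignment, marker_direction=direction)
    truth.profiles = pd.DataFrame(profiles, index=genes, columns=cell_types)  # noise-free means
    return BetaMatrix(values), sheet, truth


# ---------------------------------------------------------------------------
# bulk mixtures
# ---------------------------------------------------------------------------

def _as_profile_frame(reference) -> pd.DataFrame:
    """Accept a gene x cell-type DataFrame or a SignatureMatrix-like object."""
    if hasattr(reference, "means"):
        return reference.means
    if isinstance(reference, BetaMatrix):
        return reference.values
    return pd.DataFrame(reference)


def default_background(profiles: pd.DataFrame, offset_sd: float = 0.05,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Non-immune background: gene-wise mean of the reference profiles plus an
    independent per-gene offset, clipped to [0, 1]."""
    rng = rng or _rng(None)
    base = profiles.to_numpy().mean(axis=1)
    return np.clip(base + rng.normal(0.0, offset_sd, size=len(base)), 0.0, 1.0)


def mix_samples(
    profiles: pd.DataFrame,
    fractions: np.ndarray,
    nonimmune_mass: np.ndarray,
    noise_sd: float = 0.0,
    background: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    sample_ids: Sequence[str] | None = None,
) -> BetaMatrix:
    """Convolve cell-type profiles with given fractions.

    beta_sample = profiles @ fractions + m * background + N(0, noise_sd),
    clipped to [0, 1]; ``fractions`` rows must already include the (1 - m)
    immune scaling, i.e. sum to 1 - m.
    """
    profiles = _as_profile_frame(profiles)
    fractions = np.asarray(fractions, dtype=float)
    nonimmune_mass = np.asarray(nonimmune_mass, dtype=float)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    n_samples = fractions.shape[0]
    if fractions.shape[1] != profiles.shape[1]:
        raise ValidationError("fractions width must match number of cell types")
    rng = rng or _rng(None)
    if background is None:
        background = default_background(profiles, rng=rng)
    X = profiles.to_numpy()
    clean = X @ fractions.T + background[:, None] * nonimmune_mass[None, :]
    if noise_sd > 0:
        clean = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    clean = np.clip(clean, 0.0, 1.0)
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    return BetaMatrix(pd.DataFrame(clean, index=profiles.index, columns=list(sample_ids)))


def _subtype_means(base_mean: np.ndarray, shifts: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    out = {}
    for label, shift in shifts.items():
        m = np.clip(base_mean + np.asarray(shift, dtype=float), 1e-4, None)
        out[label] = m / m.sum()
    return out


def generate_mixtures(
    reference,
    n_samples: int,
    dirichlet_alpha: float | Sequence[float] = 1.0,
    nonimmune_mass: tuple[float, float] | float = (0.1, 0.3),
    noise_sd: float = 0.05,
    subtype_shifts: Mapping[str, Sequence[float]] | None = None,
    concentration: float = 300.0,
    sample_prefix: str = "s",
    seed: int | None = None,
) -> tuple[BetaMatrix, SyntheticTruth]:
    """Draw bulk mixtures of the reference cell types.

    Immune composition per sample is Dirichlet; a non-immune mass m drawn
    uniformly from ``nonimmune_mass`` scales the immune part down to sum
    1 - m and adds m of a background profile. When ``subtype_shifts`` is
    given, samples are split evenly across subtypes and each subtype's
    Dirichlet mean is the base mean plus its shift (renormalized), at the
    given concentration.
    """
    profiles = _as_profile_frame(reference)
    n_types = profiles.shape[1]
    rng = _rng(seed)
    alpha = np.broadcast_to(np.asarray(dirichlet_alpha, dtype=float), (n_types,)).copy()
    if np.isscalar(nonimmune_mass) or np.ndim(nonimmune_mass) == 0:
        mass = np.full(n_samples, float(nonimmune_mass))
    else:
        lo, hi = nonimmune_mass
        mass = rng.uniform(lo, hi, size=n_samples)

    sample_ids = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    if subtype_shifts:
        base_mean = alpha / alpha.sum()
        means = _subtype_means(base_mean, subtype_shifts)
        labels = [lab for i, lab in zip(range(n_samples),
                                        np.resize(list(subtype_shifts), n_samples))]
        comp = np.empty((n_samples, n_types))
        for i, lab in enumerate(labels):
            comp[i] = rng.dirichlet(concentration * means[lab])
        planted = pd.Series(labels, index=sample_ids, name="subtype")
        effects = pd.DataFrame(
            {lab: means[lab] - base_mean for lab in subtype_shifts}, index=profiles.columns
        ).T
    else:
        comp = rng.dirichlet(alpha, size=n_samples)
        planted, effects = None, None

    fractions = comp * (1.0 - mass)[:, None]
    beta = mix_samples(profiles, fractions, mass, noise_sd=noise_sd, rng=rng,
                       sample_ids=sample_ids)
    truth = SyntheticTruth(
        true_fractions=pd.DataFrame(fractions, index=sample_ids, columns=profiles.columns),
        nonimmune_mass=pd.Series(mass, index=sample_ids, name="nonimmune_mass"),
        planted_subtype=planted,
        planted_effects=effects,
    )
    return beta, truth


# ---------------------------------------------------------------------------
# expression and clinical
# ---------------------------------------------------------------------------

def generate_expression(meth: BetaMatrix, coupling_rho: float = -0.5,
                        mean_range: tuple[float, float] = (2.0, 10.0),
                        seed: int | None = None) -> pd.DataFrame:
    """Expression coupled to methylation gene-by-gene.

    Per gene the (log-scale) expression is rho * z(beta) + sqrt(1 - rho^2) * N(0,1)
    rescaled to a gene-specific mean, so the population Pearson correlation with
    beta equals ``coupling_rho`` exactly. Genes with zero beta variance get pure
    noise.
    """
    if abs(coupling_rho) > 1:
        raise ValidationError("|coupling_rho| must be <= 1")
    rng = _rng(seed)
    B = meth.values.to_numpy()
    mu = B.mean(axis=1, keepdims=True)
    sd = B.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (B - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    noise = rng.normal(size=B.shape)
    e = coupling_rho * z + np.sqrt(max(0.0, 1.0 - coupling_rho ** 2)) * noise
    gene_mu = rng.uniform(*mean_range, size=(B.shape[0], 1))
    expr = gene_mu + e
    return pd.DataFrame(expr, index=meth.values.index, columns=meth.values.columns)


def generate_survival(subtypes: Mapping | pd.Series,
                      hazard_by_subtype: Mapping[str, float],
                      censor_rate: float = 0.0,
                      seed: int | None = None) -> pd.DataFrame:
    """Exponential event times with subtype-specific hazards (per day) and
    independent exponential right-censoring."""
    subtypes = pd.Series(subtypes)
    unknown = set(subtypes.unique()) - set(hazard_by_subtype)
    if unknown:
        raise ValidationError(f"no hazard for subtype(s) {sorted(map(str, unknown))}")
    if any(h <= 0 for h in hazard_by_subtype.values()) or censor_rate < 0:
        raise ValidationError("hazards must be > 0 and censor_rate >= 0")
    rng = _rng(seed)
    hazards = subtypes.map(hazard_by_subtype).to_numpy(dtype=float)
    t_event = rng.exponential(1.0 / hazards)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, size=len(subtypes))
    else:
        t_cens = np.full(len(subtypes), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({
        "sample_id": subtypes.index,
        "survival_time": time,
        "event": event,
    })


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study conditions for the bundled synthetic cohort.

    Defaults: a 7-type x 6-replicate reference panel over 2000 genes with 50
    planted markers per type (contrast 0.4, replicate noise 0.02); two
    pseudo-cancers of 200 tumors + 50 normals each; three planted tumor
    subtypes per cancer, each shifting one cell type's mean fraction by +0.15;
    measurement noise 0.05 on the beta scale and a non-immune mass U(0.1, 0.3);
    expression coupled to methylation at rho = -0.5; subtype hazard ratio 2
    between adjacent subtypes.
    """

    n_cell_types: int = 7
    n_replicates: int = 6
    n_genes: int = 2000
    n_markers_per_type: int = 50
    marker_delta: float = 0.4
    replicate_sd: float = 0.02
    cancer_types: tuple[str, ...] = ("CAN1", "CAN2")
    n_tumor: int = 200
    n_normal: int = 50
    n_subtypes: int = 3
    subtype_shift: float = 0.15
    dirichlet_concentration: float = 300.0
    nonimmune_mass: tuple[float, float] = (0.1, 0.3)
    noise_sd: float = 0.05
    coupling_rho: float = -0.5
    base_hazard: float = 0.002          # events per day
    hazard_ratio: float = 2.0           # between adjacent subtypes
    censor_rate: float = 0.0005
    n_stages: int = 4


@dataclass
class SyntheticCohort:
    reference: BetaMatrix
    reference_sheet: SampleSheet
    profiles: pd.DataFrame              # noise-free per-type mean betas
    bulk: BetaMatrix                    # tumors + normals, all cancers
    sheet: SampleSheet
    expression: pd.DataFrame
    clinical: pd.DataFrame
    truth: SyntheticTruth
    config: CohortConfig

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_matrix(self.reference, outdir / "reference_beta.tsv")
        write_table(self.reference_sheet.table.reset_index(drop=True),
                    outdir / "reference_sheet.tsv")
        write_matrix(self.profiles, outdir / "true_profiles.tsv")
        write_matrix(self.bulk, outdir / "bulk_beta.tsv")
        write_table(self.sheet.table.reset_index(drop=True), outdir / "sample_sheet.tsv")
        write_matrix(self.expression, outdir / "expression.tsv")
        write_table(self.clinical, outdir / "clinical.tsv")
        write_matrix(self.truth.true_fractions, outdir / "true_fractions.tsv",
                     index_label="sample_id")
        write_table(self.truth.planted_subtype.rename("subtype").rename_axis("sample_id")
                    .reset_index(), outdir / "true_subtypes.tsv")
        marker_tab = pd.DataFrame({
            "gene_id": self.truth.marker_assignment.index,
            "cell_type": self.truth.marker_assignment.to_numpy(),
            "direction": self.truth.marker_direction.to_numpy(),
        })
        write_table(marker_tab[marker_tab["cell_type"].notna()], outdir / "true_markers.tsv")
        (outdir / "cohort_config.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(self.config), sort_keys=True))


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None
                    ) -> SyntheticCohort:
    """One call yielding every input the pipeline consumes, plus ground truth.

    Tumors of pseudo-cancer c, subtype s shift cell type (s + c) mod J up by
    ``subtype_shift``; normals follow the unshifted base composition, so
    planted tumor-vs-normal contrasts exist for annotation to recover.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(4 + 2 * len(config.cancer_types))]

    reference, ref_sheet, ref_truth = generate_reference_panel(
        n_cell_types=config.n_cell_types, n_replicates=config.n_replicates,
        n_genes=config.n_genes, n_markers_per_type=config.n_markers_per_type,
        marker_delta=config.marker_delta, replicate_sd=config.replicate_sd,
        seed=seeds[0])
    profiles = ref_truth.profiles
    cell_types = list(profiles.columns)
    J = len(cell_types)

    blocks, sheets, frac_blocks, mass_blocks = [], [], [], []
    subtype_labels = {}
    effects_rows = {}
    for c_idx, cancer in enumerate(config.cancer_types):
        shifts = {}
        for s in range(config.n_subtypes):
            vec = np.zeros(J)
            vec[(s + c_idx) % J] = config.subtype_shift
            shifts[f"{cancer}:{s + 1}"] = vec
        tum_beta, tum_truth = generate_mixtures(
            profiles, config.n_tumor, dirichlet_alpha=1.0,
            nonimmune_mass=config.nonimmune_mass, noise_sd=config.noise_sd,
            subtype_shifts=shifts, concentration=config.dirichlet_concentration,
            sample_prefix=f"{cancer}_T", seed=seeds[4 + 2 * c_idx])
        norm_beta, norm_truth = generate_mixtures(
            profiles, config.n_normal, dirichlet_alpha=config.dirichlet_concentration / J,
            nonimmune_mass=config.nonimmune_mass, noise_sd=config.noise_sd,
            sample_prefix=f"{cancer}_N", seed=seeds[5 + 2 * c_idx])
        blocks += [tum_beta.values, norm_beta.values]
        frac_blocks += [tum_truth.true_fractions, norm_truth.true_fractions]
        mass_blocks += [tum_truth.nonimmune_mass, norm_truth.nonimmune_mass]
        subtype_labels.update(tum_truth.planted_subtype.to_dict())
        effects_rows.update({k: v for k, v in tum_truth.planted_effects.iterrows()})
        sheets.append(pd.DataFrame({
            "sample_id": tum_beta.sample_ids + norm_beta.sample_ids,
            "group": ["tumor"] * config.n_tumor + ["normal"] * config.n_normal,
            "cancer_type": cancer,
        }))

    bulk = BetaMatrix(pd.concat(blocks, axis=1))
    sheet_df = pd.concat(sheets, ignore_index=True)
    true_fractions = pd.concat(frac_blocks, axis=0)
    planted = pd.Series(subtype_labels, name="subtype").reindex(
        [s for s in bulk.sample_ids if s in subtype_labels])

    expression = generate_expression(bulk, coupling_rho=config.coupling_rho, seed=seeds[1])

    hazards = {lab: config.base_hazard / (config.hazard_ratio ** int(lab.split(":")[1]))
               for lab in planted.unique()}
    clinical = generate_survival(planted, hazards, censor_rate=config.censor_rate,
                                 seed=seeds[2])
    # ordinal stage loosely tied to subtype index; tumor size grows with stage
    rng = _rng(seeds[3])
    sub_idx = planted.str.split(":").str[1].astype(int).to_numpy()
    stage = np.clip(sub_idx + rng.integers(-1, 2, size=len(planted)), 1, config.n_stages)
    clinical["stage"] = stage
    clinical["tumor_size"] = np.round(rng.lognormal(np.log(1 + stage), 0.3), 3)

    merged = sheet_df.merge(clinical, on="sample_id", how="left")
    truth = SyntheticTruth(
        true_fractions=true_fractions,
        nonimmune_mass=pd.concat(mass_blocks),
        marker_assignment=ref_truth.marker_assignment,
        marker_direction=ref_truth.marker_direction,
        planted_subtype=planted,
        planted_effects=pd.DataFrame(effects_rows).T,
        survival_params=hazards,
    )
    return SyntheticCohort(
        reference=reference, reference_sheet=ref_sheet, profiles=profiles,
        bulk=bulk, sheet=SampleSheet(merged), expression=expression,
        clinical=clinical, truth=truth, config=config)
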