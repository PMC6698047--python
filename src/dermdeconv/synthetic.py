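"""Synthetic reference compendia, mixtures, and cohorts with known truth.

The generator emulates the statistical structure of RMA-normalized
microarray compendia used for signature building and of bulk skin biopsy
cohorts used for deconvolution:

* a labeled reference: per-probe baseline log2 intensities drawn from a
  normal distribution (log-normal on the linear scale), disjoint marker
  blocks elevated by a fixed log2 effect in their own cell type, and
  replicate noise additive on the log2 scale;
* bulk mixtures: non-negative combinations of the true linear cell-type
  profiles with multiplicative log-normal noise;
* cross-platform shifts: per-probe gain/offset on log2 values plus probe
  dropout;
* cohorts: per-phenotype composition means on the simplex, Dirichlet
  sampling for independent samples and a shared logistic-normal subject
  effect for paired arms, with optional timepoint trajectories.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .signature import ReferenceDataset

DEFAULT_GAIN_SD = 0.05
DEFAULT_OFFSET_SD = 0.3
DEFAULT_DROPOUT = 0.1


@dataclass
class GeneratorConfig:
    """Knobs for the synthetic reference and mixture generators.

    Defaults give clean, well-separated marker blocks (16-fold marker
    elevation) with realistic microarray replicate noise, so that
    self-deconvolution of reference material is near-perfect while noisy
    mixtures remain a non-trivial recovery problem.
    """

    n_cell_types: int = 6
    n_probes: int = 400
    markers_per_type: int = 20
    marker_log2_effect: float = 4.0
    replicate_count: int = 4
    replicate_noise_sd_log2: float = 0.25
    mixture_noise_sd_log2: float = 0.2
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    dirichlet_concentration: tuple[float, ...] | None = None  # default flat (1,...,1)
    gain_sd: float = DEFAULT_GAIN_SD
    offset_sd: float = DEFAULT_OFFSET_SD
    dropout_fraction: float = DEFAULT_DROPOUT
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cell_types, self.n_probes, self.markers_per_type, self.replicate_count) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.replicate_noise_sd_log2, self.mixture_noise_sd_log2) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.markers_per_type * self.n_cell_types > self.n_probes:
            raise ValueError("marker allocation infeasible: markers_per_type * n_cell_types > n_probes")

    @property
    def cell_types(self) -> list[str]:
        return [f"type{i + 1}" for i in range(self.n_cell_types)]


@dataclass
class GroundTruth:
    """What the generator planted: the true signature and true fractions."""

    signature: pd.DataFrame  # probes x cell types, linear scale
    marker_probes: dict[str, list[str]]
    fractions: pd.DataFrame | None = None  # samples x cell types, simplex rows
    effects: dict = field(default_factory=dict)


def generate_reference(config: GeneratorConfig) -> tuple[ReferenceDataset, GroundTruth]:
    """Labeled reference compendium with planted marker blocks."""
    rng = np.random.default_rng(config.seed)
    probes = [f"probe{i + 1}" for i in range(config.n_probes)]
    types = config.cell_types
    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_probes)
    # log2 mean profile per type: baseline + marker elevation in own block
    means = np.tile(base[:, None], (1, len(types)))
    marker_probes: dict[str, list[str]] = {}
    for j, ct in enumerate(types):
        block = slice(j * config.markers_per_type, (j + 1) * config.markers_per_type)
        means[block, j] += config.marker_log2_effect
        marker_probes[ct] = probes[block]

    columns, labels = {}, {}
    for j, ct in enumerate(types):
        for r in range(config.replicate_count):
            sid = f"{ct}_rep{r + 1}"
            noise = rng.normal(0.0, config.replicate_noise_sd_log2, config.n_probes)
            columns[sid] = means[:, j] + noise
            labels[sid] = ct
    expr = ExpressionMatrix(pd.DataFrame(columns, index=probes), "log2")
    truth_sig = pd.DataFrame(np.exp2(means), index=probes, columns=types)
    return ReferenceDataset(expr, labels), GroundTruth(truth_sig, marker_probes)


def generate_mixtures(
    signature: pd.DataFrame,
    n_samples: int,
    dirichlet_concentration=None,
    mixture_noise_sd_log2: float = 0.2,
    seed: int = 0,
    fractions: pd.DataFrame | None = None,
    sample_prefix: str = "mix",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Bulk mixtures m = sum_k f_k * signature_k with log-normal noise.

    ``fractions`` may supply the true composition directly (rows on the
    simplex); otherwise fractions are drawn from a Dirichlet with the given
    concentration (flat if None). Returns the linear-scale mixture matrix and
    the true fraction table.
    """
    rng = np.random.default_rng(seed)
    types = signature.columns.tolist()
    k = len(types)
    if fractions is None:
        conc = np.ones(k) if dirichlet_concentration is None else np.asarray(dirichlet_concentration, float)
        if conc.size != k:
            raise ValueError("concentration length must equal the number of cell types")
        f = rng.dirichlet(conc, size=n_samples)
        sample_ids = [f"{sample_prefix}{i + 1}" for i in range(n_samples)]
        fractions = pd.DataFrame(f, index=sample_ids, columns=types)
    else:
        fractions = fractions[types]
    clean = signature.to_numpy() @ fractions.to_numpy().T
    noise = rng.normal(0.0, mixture_noise_sd_log2, clean.shape)
    mixed = clean * np.exp2(noise)
    expr = ExpressionMatrix(
        pd.DataFrame(mixed, index=signature.index, columns=fractions.index), "linear"
    )
    return expr, fractions


def simulate_platform_shift(
    matrix: ExpressionMatrix,
    gain_sd: float = DEFAULT_GAIN_SD,
    offset_sd: float = DEFAULT_OFFSET_SD,
    dropout_fraction: float = DEFAULT_DROPOUT,
    seed: int = 0,
) -> ExpressionMatrix:
    """Cross-platform distortion: per-probe log2 gain/offset plus dropout.

    Each probe's log2 value x becomes gain * x + offset with
    gain ~ N(1, gain_sd^2), offset ~ N(0, offset_sd^2); a random
    ``dropout_fraction`` of probes is removed. The declared scale of the
    input is preserved on output.
    """
    if not 0 <= dropout_fraction < 1:
        raise ValueError("dropout_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    log2_values = matrix.data if matrix.scale == "log2" else np.log2(matrix.data)
    n = log2_values.shape[0]
    gain = rng.normal(1.0, gain_sd, n)
    offset = rng.normal(0.0, offset_sd, n)
    shifted = log2_values.mul(gain, axis=0).add(offset, axis=0)
    n_drop = int(round(dropout_fraction * n))
    if n_drop:
        drop = rng.choice(n, size=n_drop, replace=False)
        shifted = shifted.drop(index=shifted.index[drop])
    if matrix.scale == "linear":
        return ExpressionMatrix(np.exp2(shifted), "linear")
    return ExpressionMatrix(shifted, "log2")


@dataclass
class CohortArm:
    """One arm of a cohort design (a phenotype / timepoint stratum)."""

    name: str
    composition: np.ndarray  # simplex mean over the signature's cell types
    n: int
    disease: str = "psoriasis"
    lesional: str = "lesional"
    severity: str = "unknown"
    timepoint: float | None = None
    study_id: str = "study1"

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, float)
        if (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-8:
            raise ValueError(f"arm {self.name!r}: composition must lie on the simplex")
        self.composition = comp


@dataclass
class CohortConfig:
    """A paired or independent multi-arm cohort over one true signature.

    Paired designs share a per-subject logistic-normal composition effect
    across arms (subjects indexed 1..n, equal n per arm); independent designs
    draw per-sample Dirichlet compositions centered on each arm's mean with
    the given precision.
    """

    arms: list[CohortArm]
    paired: bool = True
    subject_sd_log: float = 0.15
    sample_sd_log: float = 0.10
    dirichlet_precision: float = 100.0
    mixture_noise_sd_log2: float = 0.2
    seed: int = 0


def _logistic_normal(mean: np.ndarray, perturbation: np.ndarray) -> np.ndarray:
    tilted = mean * np.exp(perturbation)
    return tilted / tilted.sum()


def generate_cohort(
    signature: pd.DataFrame, config: CohortConfig
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate a cohort of bulk mixtures with per-arm planted compositions.

    Returns (linear-scale expression, sample metadata, ground truth). In
    paired mode all arms must have equal n and subject ``subj<i>`` appears in
    every arm.
    """
    rng = np.random.default_rng(config.seed)
    k = signature.shape[1]
    for arm in config.arms:
        if arm.composition.size != k:
            raise ValueError(f"arm {arm.name!r}: composition length != number of cell types")
    if config.paired and len({arm.n for arm in config.arms}) != 1:
        raise ValueError("paired designs need equal n per arm")

    frac_rows, meta_rows, ids = [], [], []
    if config.paired:
        n = config.arms[0].n
        subject_effects = rng.normal(0.0, config.subject_sd_log, size=(n, k))
        for arm in config.arms:
            for i in range(n):
                eps = rng.normal(0.0, config.sample_sd_log, size=k)
                f = _logistic_normal(arm.composition, subject_effects[i] + eps)
                sid = f"{arm.name}_subj{i + 1}"
                ids.append(sid)
                frac_rows.append(f)
                meta_rows.append(_meta_row(sid, arm, subject=f"subj{i + 1}"))
    else:
        for arm in config.arms:
            conc = arm.composition * config.dirichlet_precision
            draws = rng.dirichlet(conc, size=arm.n)
            for i in range(arm.n):
                sid = f"{arm.name}_s{i + 1}"
                ids.append(sid)
                frac_rows.append(draws[i])
                meta_rows.append(_meta_row(sid, arm, subject=f"{arm.name}_subj{i + 1}"))

    fractions = pd.DataFrame(frac_rows, index=ids, columns=signature.columns)
    expr, _ = generate_mixtures(
        signature,
        n_samples=len(ids),
        mixture_noise_sd_log2=config.mixture_noise_sd_log2,
        seed=int(rng.integers(2**31 - 1)),
        fractions=fractions,
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    effects = {
        "arm_compositions": {arm.name: arm.composition.tolist() for arm in config.arms},
        "paired": config.paired,
    }
    return expr, metadata, GroundTruth(signature, {}, fractions, effects)


def _meta_row(sample_id: str, arm: CohortArm, subject: str) -> dict:
    return {
        "sample_id": sample_id,
        "study_id": arm.study_id,
        "disease": arm.disease,
        "lesional": arm.lesional,
        "subject_id": subject,
        "timepoint": arm.timepoint,
        "severity": arm.severity,
        "tissue_layer": "whole_skin",
        "arm": arm.name,
    }
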