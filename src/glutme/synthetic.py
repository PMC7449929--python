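"""Synthetic cohorts with the statistical structure of tumor-immune glucose competition.

Three generators produce all fixture data used to exercise the analysis
end-to-end without any external download:

* :func:`generate_bulk_cohort` — a bulk RNA-seq cohort with a latent immune
  fraction ``f`` per tumor drawn from a two-component Beta mixture (a large
  immune-poor and a smaller immune-rich mode).  Bulk GLUT1 scales with the
  cancer content ``1 - f`` and bulk GLUT3 with the immune content ``f``;
  immune cell-type signature genes scale with ``f`` and glycolysis genes with
  ``1 - f``.  The paired PET readout TLRmax is a weighted sum of the two GLUT
  contributions plus Gaussian noise — tumor glucose uptake as the sum of
  cancer-cell GLUT1 and immune-cell GLUT3 uptake.

* :func:`generate_response_cohort` — an immunotherapy cohort with paired
  pre/on-treatment samples.  The probability of a non-progressive course rises
  with the baseline GLUT-ratio; in SD and PR/CR patients the on-treatment
  log-ratio regresses toward the cohort mean (so low-baseline tumors rise),
  while in PD it only wanders.  Progression-free survival is exponential with
  a log-hazard linear in the standardized baseline log-ratio.

* :func:`generate_sc_cohort` — a multi-cell-type single-cell count matrix with
  negative-binomial counts and type-restricted transporters: GLUT1 only in
  cancer cells, GLUT3 in myeloid, T and endothelial cells.

Every generator is a pure function of its parameter object: identical
parameters (including the seed) give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .enrichment import (
    GLYCOLYSIS_SIGNATURE,
    IMMUNE_SUMMAND_TYPES,
    SignatureCollection,
)
from .exceptions import ParameterError
from .response import COHORT_COLUMNS
from .sc import GLUT1_GENE, GLUT3_GENE
from .stratification import IMMUNE_POOR, IMMUNE_RICH

# ---------------------------------------------------------------------------
# Bulk cohort
# ---------------------------------------------------------------------------


@dataclass
class BulkSimParams:
    """Parameters of the bulk tumor cohort generator.

    The defaults describe a cohort resembling resected lung squamous cell
    carcinoma: roughly 70% immune-poor tumors (immune fraction around
    Beta(2, 8), mean 0.2) and 30% immune-rich tumors (Beta(8, 3), mean 0.73),
    with TLRmax on the 1-10 range typical of liver-normalized FDG uptake.
    """

    n_samples: int = 200
    n_genes: int = 500
    immune_mix_weight: float = 0.7  # weight of the immune-poor component
    poor_beta: tuple[float, float] = (2.0, 8.0)
    rich_beta: tuple[float, float] = (8.0, 3.0)
    glut1_cancer_mean: float = 50.0
    glut3_immune_mean: float = 40.0
    pet_coefs: tuple[float, float, float] = (0.5, 0.15, 0.15)  # (c0, c1, c3)
    pet_noise_sd: float = 0.3
    signature_size: int = 15
    expr_noise_sd: float = 0.25  # sd of the multiplicative lognormal noise
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ParameterError("n_samples must be at least 4")
        required = (len(IMMUNE_SUMMAND_TYPES) + 1) * self.signature_size + 2
        if self.n_genes <= required:
            raise ParameterError(
                f"n_genes must exceed {required} to hold the signatures, the two GLUT genes and filler genes"
            )
        if not 0 <= self.immune_mix_weight <= 1:
            raise ParameterError("immune_mix_weight must lie in [0, 1]")
        if self.signature_size < 1:
            raise ParameterError("signature_size must be positive")
        if min(*self.poor_beta, *self.rich_beta) <= 0:
            raise ParameterError("Beta shape parameters must be positive")
        if self.glut1_cancer_mean <= 0 or self.glut3_immune_mean <= 0:
            raise ParameterError("GLUT expression means must be positive")
        if any(c < 0 for c in self.pet_coefs) or self.pet_noise_sd < 0:
            raise ParameterError("PET coefficients and noise sd must be nonnegative")


@dataclass
class BulkCohort:
    """A simulated bulk cohort with its latent truth.

    ``expression`` is the log-normalized genes x samples matrix;
    ``samples`` holds one row per sample with the latent immune fraction,
    the paired TLRmax readout and the true mixture-component cluster label.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame  # columns: immune_fraction, tlr_max, cluster_truth
    signatures: SignatureCollection
    crossing_point: float | None = field(default=None)

    @property
    def immune_fraction_truth(self) -> pd.Series:
        return self.samples["immune_fraction"]

    @property
    def tlr_max(self) -> pd.Series:
        return self.samples["tlr_max"]

    @property
    def cluster_truth(self) -> pd.Series:
        return self.samples["cluster_truth"]

    def features(self) -> pd.DataFrame:
        """Samples x metabolic-feature table (GLUT1, GLUT3, TLRmax) for correlation panels."""
        return pd.DataFrame(
            {
                "GLUT1": self.expression.loc[GLUT1_GENE],
                "GLUT3": self.expression.loc[GLUT3_GENE],
                "TLRmax": self.samples["tlr_max"],
            }
        )


def default_bulk_signatures(signature_size: int = 15) -> SignatureCollection:
    """The generator's signature collection: 10 immune cell types plus glycolysis."""
    sets = {
        cell_type: [f"{cell_type}_{k:02d}" for k in range(signature_size)]
        for cell_type in IMMUNE_SUMMAND_TYPES
    }
    sets[GLYCOLYSIS_SIGNATURE] = [f"GLYC_{k:02d}" for k in range(signature_size)]
    return SignatureCollection(sets=sets, immune_summands=IMMUNE_SUMMAND_TYPES)


def _mixture_crossing_point(params: BulkSimParams) -> float | None:
    """Point where the weighted component densities of the immune-fraction mixture cross.

    Solves ``w * Beta(poor) = (1 - w) * Beta(rich)`` between the component
    means; samples above the crossing are more likely immune-rich than
    immune-poor.  Returns None when the mixture is degenerate (w = 0 or 1).
    """
    w = params.immune_mix_weight
    if w in (0.0, 1.0):
        return None
    ap, bp = params.poor_beta
    ar, br = params.rich_beta
    lo = ap / (ap + bp)
    hi = ar / (ar + br)
    if lo > hi:
        lo, hi = hi, lo

    def g(x: float) -> float:
        return w * stats.beta.pdf(x, ap, bp) - (1 - w) * stats.beta.pdf(x, ar, br)

    grid = np.linspace(lo, hi, 512)
    vals = np.array([g(x) for x in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        # one component dominates everywhere between the means
        return float((lo + hi) / 2.0)
    i = sign_change[0]
    return float(optimize.brentq(g, grid[i], grid[i + 1]))


def generate_bulk_cohort(params: BulkSimParams | None = None) -> BulkCohort:
    """Simulate a bulk cohort with paired PET readouts. See the module docstring."""
    params = params or BulkSimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_samples

    # latent immune fraction from the two-component Beta mixture
    is_poor = rng.random(n) < params.immune_mix_weight
    f_poor = rng.beta(*params.poor_beta, size=n)
    f_rich = rng.beta(*params.rich_beta, size=n)
    f = np.where(is_poor, f_poor, f_rich)

    crossing = _mixture_crossing_point(params)
    if crossing is None:
        labels = np.full(n, IMMUNE_POOR if params.immune_mix_weight == 1.0 else IMMUNE_RICH)
    else:
        labels = np.where(f > crossing, IMMUNE_RICH, IMMUNE_POOR)

    signatures = default_bulk_signatures(params.signature_size)
    signature_genes = [g for name in signatures for g in signatures[name]]
    n_filler = params.n_genes - len(signature_genes) - 2
    gene_ids = [GLUT1_GENE, GLUT3_GENE, *signature_genes] + [f"FILLER_{k:04d}" for k in range(n_filler)]
    sample_ids = [f"S{j:04d}" for j in range(n)]

    # per-gene base levels and per-sample scaling factors
    base = np.empty(len(gene_ids))
    base[0] = params.glut1_cancer_mean
    base[1] = params.glut3_immune_mean
    base[2 : 2 + len(signature_genes)] = rng.uniform(20.0, 60.0, size=len(signature_genes))
    base[2 + len(signature_genes) :] = rng.uniform(5.0, 50.0, size=n_filler)

    factor = np.ones((len(gene_ids), n))
    factor[0] = 1.0 - f  # bulk GLUT1 tracks cancer content
    factor[1] = f  # bulk GLUT3 tracks immune content
    row = 2
    for name in signatures:
        scale = f if name in signatures.immune_summands else (1.0 - f)
        factor[row : row + params.signature_size] = scale
        row += params.signature_size

    noise = np.exp(rng.normal(0.0, params.expr_noise_sd, size=(len(gene_ids), n)))
    raw = base[:, None] * factor * noise
    expression = pd.DataFrame(np.log1p(raw), index=gene_ids, columns=sample_ids)

    # PET uptake: weighted sum of the cancer-cell GLUT1 and immune-cell GLUT3
    # contributions (the bulk raw levels already carry the 1-f / f weights)
    c0, c1, c3 = params.pet_coefs
    tlr = c0 + c1 * raw[0] + c3 * raw[1] + rng.normal(0.0, params.pet_noise_sd, size=n)
    tlr = np.maximum(tlr, 0.01)

    samples = pd.DataFrame(
        {"immune_fraction": f, "tlr_max": tlr, "cluster_truth": labels},
        index=sample_ids,
    )
    return BulkCohort(expression=expression, samples=samples, signatures=signatures, crossing_point=crossing)


# ---------------------------------------------------------------------------
# Immunotherapy response cohort
# ---------------------------------------------------------------------------


@dataclass
class ResponseSimParams:
    """Parameters of the immunotherapy response-cohort generator.

    The baseline log GLUT-ratio is Normal(ratio_logmean, ratio_logsd); the
    probability of a non-progressive course (SD or PR/CR) is
    ``logistic(response_intercept + response_slope * z(baseline))``, and
    non-progressors split PR/CR vs SD with probability ``prcr_fraction``.
    ``change_pullback`` is the regression-to-the-mean strength of the
    on-treatment log-ratio in SD and PR/CR patients (0 = no treatment effect,
    1 = full return to the cohort mean).  PFS is exponential with hazard
    ``hazard_scale * exp(hazard_coef * z(baseline))`` (times in months),
    censored at ``censor_horizon``.
    """

    n_patients: int = 200
    ratio_logmean: float = 0.0
    ratio_logsd: float = 0.8
    response_intercept: float = 0.0
    response_slope: float = 0.8
    prcr_fraction: float = 0.5
    change_pullback: float = 0.6
    on_noise_sd: float = 0.15
    hazard_scale: float = 0.08  # events per month at z = 0
    hazard_coef: float = -0.3  # log-hazard per unit z of the baseline log-ratio
    censor_horizon: float = 36.0
    glut1_logmean: float = 1.5
    glut1_logsd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 10:
            raise ParameterError("n_patients must be at least 10")
        if self.hazard_scale <= 0:
            raise ParameterError("hazard_scale must be positive")
        if self.ratio_logsd <= 0:
            raise ParameterError("ratio_logsd must be positive")
        if self.change_pullback < 0 or self.on_noise_sd < 0:
            raise ParameterError("change_pullback and on_noise_sd must be nonnegative")
        if not 0 <= self.prcr_fraction <= 1:
            raise ParameterError("prcr_fraction must lie in [0, 1]")
        if self.censor_horizon <= 0:
            raise ParameterError("censor_horizon must be positive")


@dataclass
class ResponseCohortSim:
    """Simulated response cohort: the analysis-facing table plus latent truth."""

    data: pd.DataFrame  # long format, see response.COHORT_COLUMNS
    truth: pd.DataFrame  # per patient: baseline_logratio, z, on_logratio


def generate_response_cohort(params: ResponseSimParams | None = None) -> ResponseCohortSim:
    """Simulate paired pre/on-treatment GLUT expression with response and PFS."""
    params = params or ResponseSimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    baseline = rng.normal(params.ratio_logmean, params.ratio_logsd, size=n)
    z = (baseline - params.ratio_logmean) / params.ratio_logsd

    p_nonpd = expit(params.response_intercept + params.response_slope * z)
    nonpd = rng.random(n) < p_nonpd
    prcr = nonpd & (rng.random(n) < params.prcr_fraction)
    response = np.where(prcr, "PR_CR", np.where(nonpd, "SD", "PD"))

    pullback = np.where(nonpd, params.change_pullback * (baseline - params.ratio_logmean), 0.0)
    on = baseline - pullback + rng.normal(0.0, params.on_noise_sd, size=n)

    rate = params.hazard_scale * np.exp(params.hazard_coef * z)
    t = rng.exponential(1.0 / rate)
    event = t <= params.censor_horizon
    pfs = np.minimum(t, params.censor_horizon)

    # realize the log-ratio as a GLUT3/GLUT1 pair of positive expression values
    glut1 = np.exp(rng.normal(params.glut1_logmean, params.glut1_logsd, size=(2, n)))
    glut3 = glut1 * np.exp(np.vstack([baseline, on]))

    patient_ids = [f"P{j:04d}" for j in range(n)]
    rows = []
    for tp_idx, tp in enumerate(("pre", "on")):
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": patient_ids,
                    "timepoint": tp,
                    "glut1": glut1[tp_idx],
                    "glut3": glut3[tp_idx],
                    "response": response,
                    "pfs_time": pfs,
                    "event": event,
                }
            )
        )
    data = pd.concat(rows, ignore_index=True)[list(COHORT_COLUMNS)]
    truth = pd.DataFrame(
        {"baseline_logratio": baseline, "z": z, "on_logratio": on},
        index=pd.Index(patient_ids, name="patient_id"),
    )
    return ResponseCohortSim(data=data, truth=truth)


# ---------------------------------------------------------------------------
# Single-cell cohort
# ---------------------------------------------------------------------------

SC_CELL_TYPES = ("cancer", "myeloid", "t_cell", "endothelial", "fibroblast")
SC_GENE_GROUPS = ("glut1", "glut3", "marker", "glycolysis", "oxphos", "housekeeping")
GLUT3_CELL_TYPES = ("myeloid", "t_cell", "endothelial")


def default_sc_means() -> dict[str, dict[str, float]]:
    """Per-(cell type, gene group) negative-binomial mean counts at library-size 1.

    GLUT1 is restricted to cancer cells and GLUT3 to myeloid, T and
    endothelial cells; glycolysis genes are highest in cancer, oxidative
    phosphorylation higher in the immune/stromal compartment.  ``marker``
    means apply only to the cell type's own marker genes (other types express
    them at the ``marker_background`` level).
    """
    return {
        "cancer": {"glut1": 5.0, "glut3": 0.0, "marker": 8.0, "glycolysis": 6.0, "oxphos": 2.0, "housekeeping": 5.0},
        "myeloid": {"glut1": 0.0, "glut3": 1.5, "marker": 8.0, "glycolysis": 2.0, "oxphos": 6.0, "housekeeping": 5.0},
        "t_cell": {"glut1": 0.0, "glut3": 1.0, "marker": 8.0, "glycolysis": 1.5, "oxphos": 4.0, "housekeeping": 5.0},
        "endothelial": {"glut1": 0.0, "glut3": 0.8, "marker": 8.0, "glycolysis": 1.5, "oxphos": 4.0, "housekeeping": 5.0},
        "fibroblast": {"glut1": 0.0, "glut3": 0.0, "marker": 8.0, "glycolysis": 1.5, "oxphos": 4.0, "housekeeping": 5.0},
    }


def _default_type_proportions() -> dict[str, float]:
    return {"cancer": 0.2, "myeloid": 0.3, "t_cell": 0.3, "endothelial": 0.1, "fibroblast": 0.1}


@dataclass
class ScSimParams:
    """Parameters of the single-cell count-matrix generator.

    Counts are negative-binomial (Gamma-Poisson) with dispersion
    ``nb_dispersion`` (variance ``mu + mu^2 / dispersion``); setting the
    dispersion to ``math.inf`` gives the Poisson limit.  Each cell carries a
    lognormal library-size factor multiplying all its gene means.
    """

    n_cells: int = 2000
    type_proportions: dict[str, float] = field(default_factory=_default_type_proportions)
    type_expression_means: dict[str, dict[str, float]] = field(default_factory=default_sc_means)
    marker_background: float = 0.2
    markers_per_type: int = 10
    set_size: int = 10  # glycolysis / oxphos set sizes
    n_housekeeping: int = 20
    nb_dispersion: float = 2.0
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 100:
            raise ParameterError("n_cells must be at least 100")
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"type_proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.type_proportions.values()):
            raise ParameterError("type_proportions must be nonnegative")
        unknown = set(self.type_proportions) - set(self.type_expression_means)
        if unknown:
            raise ParameterError(f"no expression means for cell types: {sorted(unknown)}")
        for ct, groups in self.type_expression_means.items():
            missing = set(SC_GENE_GROUPS) - set(groups)
            if missing:
                raise ParameterError(f"cell type {ct!r} lacks means for groups {sorted(missing)}")
            if any(m < 0 for m in groups.values()):
                raise ParameterError("expression means must be nonnegative")
        if not (self.nb_dispersion > 0):
            raise ParameterError("nb_dispersion must be positive (math.inf for the Poisson limit)")


@dataclass
class ScCohort:
    """Simulated single-cell cohort: raw counts, labels and the gene groups."""

    counts: pd.DataFrame  # cells x genes, integer counts
    cell_types: pd.Series
    gene_groups: dict[str, list[str]]
    libsize_factors: pd.Series


def generate_sc_cohort(params: ScSimParams | None = None) -> ScCohort:
    """Simulate a multi-cell-type count matrix with type-restricted GLUTs."""
    params = params or ScSimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    cell_types_present = [ct for ct in params.type_proportions if params.type_proportions[ct] > 0]
    gene_groups: dict[str, list[str]] = {"glut1": [GLUT1_GENE], "glut3": [GLUT3_GENE]}
    for ct in params.type_expression_means:
        gene_groups[f"marker:{ct}"] = [f"{ct.upper()}_MARK_{k:02d}" for k in range(params.markers_per_type)]
    gene_groups["glycolysis"] = [f"GLYC_{k:02d}" for k in range(params.set_size)]
    gene_groups["oxphos"] = [f"OXPHOS_{k:02d}" for k in range(params.set_size)]
    gene_groups["housekeeping"] = [f"HK_{k:02d}" for k in range(params.n_housekeeping)]
    gene_ids = [g for genes in gene_groups.values() for g in genes]

    probs = np.array([params.type_proportions[ct] for ct in cell_types_present])
    type_idx = rng.choice(len(cell_types_present), size=params.n_cells, p=probs)
    cell_types = np.array(cell_types_present)[type_idx]
    libsize = np.exp(rng.normal(params.libsize_logmean, params.libsize_logsd, size=params.n_cells))

    # per-cell-type mean vector over genes
    type_means = {}
    for ct in cell_types_present:
        groups = params.type_expression_means[ct]
        mu = []
        for group, genes in gene_groups.items():
            if group.startswith("marker:"):
                level = groups["marker"] if group == f"marker:{ct}" else params.marker_background
            else:
                level = groups[group]
            mu.extend([level] * len(genes))
        type_means[ct] = np.asarray(mu)

    mu = np.vstack([type_means[ct] for ct in cell_types]) * libsize[:, None]
    if math.isinf(params.nb_dispersion):
        counts = rng.poisson(mu)
    else:
        lam = np.zeros_like(mu)
        pos = mu > 0
        lam[pos] = rng.gamma(shape=params.nb_dispersion, scale=mu[pos] / params.nb_dispersion)
        counts = rng.poisson(lam)

    cell_ids = [f"C{j:05d}" for j in range(params.n_cells)]
    return ScCohort(
        counts=pd.DataFrame(counts, index=cell_ids, columns=gene_ids, dtype=np.int64),
        cell_types=pd.Series(cell_types, index=cell_ids, name="cell_type"),
        gene_groups=gene_groups,
        libsize_factors=pd.Series(libsize, index=cell_ids, name="libsize_factor"),
    )
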