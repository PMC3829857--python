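"""Seeded generators for synthetic pipeline inputs.

Each generator is a pure function of its parameters and seed and emits data
with the statistical structure the downstream stage assumes: paired PP/PN
cohorts with study blocks and planted log2 effects, a keratinocyte/epidermis
reference matrix with latent-factor co-expression modules, small two-group
perturbation experiments, paired methylation M-values with planted biased
genes, and gene-adjacent sequences with planted IUPAC motif occurrences whose
frequency can be confounded with sequence length.

Noise is Gaussian on the log2 scale; study offsets are Gaussian per
(study, gene), consistent with a design in which each lesional sample is
compared only to its paired control from the same patient and study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from psormod.datatypes import ExpressionMatrix, MotifModel, IUPAC_CODES

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# paired PP/PN cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortTruth:
    """Ground truth for a synthetic paired cohort."""

    deg_up: set[str]
    deg_down: set[str]
    per_gene_effect: dict[str, float]
    study_offsets: dict[str, np.ndarray]


def gen_paired_cohort(
    n_patients: int,
    n_genes: int,
    n_studies: int = 3,
    frac_deg: float = 0.1,
    effect_size: float = 1.0,
    seed: int = 0,
    *,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    study_sd: float = 0.3,
    patient_sd: float = 0.3,
    noise_sd: float = 0.5,
    frac_above_background: float = 0.95,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Simulate a paired PP/PN cohort with study blocks and planted DEGs.

    PN log2 values are baseline + study offset + patient effect + noise; PP
    values add ``effect_size`` (``-effect_size``) for planted up (down) DEGs.
    ``frac_deg`` of genes are planted DEGs, split evenly between directions.
    Above-background flags follow a latent detection probability increasing
    with expression, calibrated so roughly ``frac_above_background`` of
    entries are flagged.
    """
    if n_patients < 2 or n_genes < 1 or n_studies < 1:
        raise ValueError("n_patients >= 2, n_genes >= 1, n_studies >= 1 required")
    if not 0.0 <= frac_deg <= 0.5:
        raise ValueError(f"frac_deg must be in [0, 0.5], got {frac_deg}")
    rng = np.random.default_rng(seed)

    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_deg = int(round(frac_deg * n_genes))
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    n_up = n_deg // 2 + n_deg % 2
    up_idx = deg_idx[:n_up]
    down_idx = deg_idx[n_up:]
    effect = np.zeros(n_genes)
    effect[up_idx] = effect_size
    effect[down_idx] = -effect_size

    studies = [f"S{j+1}" for j in range(n_studies)]
    patient_study = np.arange(n_patients) % n_studies
    baseline = rng.normal(baseline_mean, baseline_sd, n_genes)
    study_off = rng.normal(0.0, study_sd, (n_studies, n_genes))
    patient_eff = rng.normal(0.0, patient_sd, (n_patients, n_genes))

    pn = (
        baseline[None, :]
        + study_off[patient_study]
        + patient_eff
        + rng.normal(0.0, noise_sd, (n_patients, n_genes))
    )
    pp = (
        baseline[None, :]
        + study_off[patient_study]
        + patient_eff
        + effect[None, :]
        + rng.normal(0.0, noise_sd, (n_patients, n_genes))
    )

    sample_ids, meta_rows, columns = [], [], []
    for p in range(n_patients):
        pid = f"P{p:04d}"
        study = studies[patient_study[p]]
        for cond, mat in (("PP", pp), ("PN", pn)):
            sid = f"{pid}_{cond}"
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "study_id": study, "patient_id": pid,
                 "condition": cond}
            )
            columns.append(mat[p])
    values = pd.DataFrame(
        np.column_stack(columns), index=genes, columns=sample_ids
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    midpoint = np.quantile(values.to_numpy(), 1.0 - frac_above_background)
    p_detect = expit(2.0 * (values.to_numpy() - midpoint))
    flags = pd.DataFrame(
        rng.random(values.shape) < p_detect, index=genes, columns=sample_ids
    )

    truth = CohortTruth(
        deg_up={genes[i] for i in up_idx},
        deg_down={genes[i] for i in down_idx},
        per_gene_effect={g: float(e) for g, e in zip(genes, effect)},
        study_offsets={s: study_off[j] for j, s in enumerate(studies)},
    )
    expr = ExpressionMatrix(values=values, samples=meta, above_background=flags)
    return expr, truth


def gen_perturbation_experiment(
    n_genes: int,
    n_per_arm: int = 3,
    frac_responsive: float = 0.1,
    effect_size: float = 1.5,
    seed: int = 0,
    noise_sd: float = 0.4,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Small two-group (treated vs control) experiment with responsive genes.

    Mirrors a cytokine-stimulation design: 2-3 arrays per arm, a planted set
    of induced and repressed genes (``frac_responsive`` of genes, split
    evenly), unpaired groups.
    """
    if n_per_arm < 2:
        raise ValueError("need at least 2 samples per arm")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_resp = int(round(frac_responsive * n_genes))
    idx = rng.choice(n_genes, n_resp, replace=False)
    n_ind = n_resp // 2 + n_resp % 2
    effect = np.zeros(n_genes)
    effect[idx[:n_ind]] = effect_size
    effect[idx[n_ind:]] = -effect_size

    baseline = rng.normal(7.0, 1.5, n_genes)
    control = baseline[None, :] + rng.normal(0, noise_sd, (n_per_arm, n_genes))
    treated = (
        baseline[None, :] + effect[None, :]
        + rng.normal(0, noise_sd, (n_per_arm, n_genes))
    )
    cols, ids, meta_rows = [], [], []
    for i in range(n_per_arm):
        ids.append(f"CTRL{i}")
        cols.append(control[i])
        meta_rows.append({"sample_id": f"CTRL{i}", "study_id": "EXP",
                          "patient_id": f"c{i}", "condition": "control"})
    for i in range(n_per_arm):
        ids.append(f"TRT{i}")
        cols.append(treated[i])
        meta_rows.append({"sample_id": f"TRT{i}", "study_id": "EXP",
                          "patient_id": f"t{i}", "condition": "treated"})
    values = pd.DataFrame(np.column_stack(cols), index=genes, columns=ids)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = CohortTruth(
        deg_up={genes[i] for i in idx[:n_ind]},
        deg_down={genes[i] for i in idx[n_ind:]},
        per_gene_effect={g: float(e) for g, e in zip(genes, effect)},
        study_offsets={},
    )
    return ExpressionMatrix(values=values, samples=meta), truth


# ---------------------------------------------------------------------------
# co-expression module reference
# ---------------------------------------------------------------------------

@dataclass
class ModuleTruth:
    """Ground truth for the planted co-expression structure."""

    modules: dict[str, list[str]]
    factor_loadings: dict[str, tuple[str, float]]
    noise_sd: float

    def labels(self, genes: list[str]) -> np.ndarray:
        """Integer partition labels over ``genes``; 0 = background."""
        lab = {}
        for k, (mid, members) in enumerate(self.modules.items(), start=1):
            for g in members:
                lab[g] = k
        return np.array([lab.get(g, 0) for g in genes])


def gen_module_reference(
    n_samples: int,
    module_sizes: list[int],
    loading: float = 0.9,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_background: int = 0,
) -> tuple[ExpressionMatrix, ModuleTruth]:
    """Latent-factor reference matrix with planted co-expression modules.

    Genes of planted module m follow ``scale_g · loading · f_m(s)`` plus
    Gaussian noise, where f_m is a per-sample standard-normal latent factor;
    background genes are pure noise.  With ``noise_sd=0`` and ``loading=1``
    within-module profiles are identical up to per-gene scale.
    """
    if any(size < 2 for size in module_sizes):
        raise ValueError("each module size must be >= 2")
    if not 0.0 < loading <= 1.0:
        raise ValueError(f"loading must be in (0, 1], got {loading}")
    rng = np.random.default_rng(seed)
    n_genes = sum(module_sizes) + n_background
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"KC{j:03d}" for j in range(n_samples)]

    values = np.empty((n_genes, n_samples))
    modules: dict[str, list[str]] = {}
    loadings: dict[str, tuple[str, float]] = {}
    row = 0
    for m, size in enumerate(module_sizes, start=1):
        mid = f"M{m}"
        factor = rng.normal(0.0, 1.0, n_samples)
        members = genes[row : row + size]
        modules[mid] = members
        for g in members:
            scale = rng.uniform(0.5, 1.5)
            loadings[g] = (mid, loading)
            values[row] = scale * loading * factor + rng.normal(
                0.0, noise_sd, n_samples
            )
            row += 1
    values[row:] = rng.normal(0.0, 1.0, (n_background, n_samples))

    meta = pd.DataFrame(
        {"sample_id": samples, "study_id": "REF", "patient_id": samples,
         "condition": "other"}
    ).set_index("sample_id")
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), samples=meta
    )
    return expr, ModuleTruth(modules=modules, factor_loadings=loadings,
                             noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# sequences with planted motif occurrences
# ---------------------------------------------------------------------------

@dataclass
class SequenceTruth:
    """Ground truth for planted motif occurrences."""

    planted_counts: dict[str, int]
    planted_positions: dict[str, list[int]]
    lengths: dict[str, int]
    length_module_confound: float


def gen_sequences(
    n_genes: int,
    length_dist: tuple[float, float],
    motif: MotifModel,
    enriched_set: set[str],
    rate_in: float,
    rate_out: float,
    confound: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, np.ndarray], SequenceTruth]:
    """Random sequences with planted exact-IUPAC motif occurrences.

    Occurrence counts are Poisson with per-kilobase rate ``rate_in`` for
    genes in ``enriched_set`` and ``rate_out`` otherwise.  ``confound > 0``
    lengthens enriched-set sequences by a factor ``1 + confound``, coupling
    membership to sequence length.  Per-base conservation scores are uniform
    with an elevated mean inside planted sites.

    Gene ids are ``G00000``..; ``enriched_set`` must use the same ids.
    """
    if rate_in < 0 or rate_out < 0 or confound < 0:
        raise ValueError("rates and confound must be non-negative")
    mean_len, sd_len = length_dist
    rng = np.random.default_rng(seed)
    m = motif.length
    if m + 10 > mean_len - 3 * sd_len:
        raise ValueError(
            f"motif length {m} too long for length distribution {length_dist}"
        )
    genes = [f"G{i:05d}" for i in range(n_genes)]
    seqs: dict[str, str] = {}
    scores: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    positions: dict[str, list[int]] = {}
    lengths: dict[str, int] = {}
    for g in genes:
        enriched = g in enriched_set
        mu = mean_len * (1.0 + confound) if enriched else mean_len
        length = max(int(round(rng.normal(mu, sd_len))), m + 10)
        seq = rng.choice(4, size=length)
        rate = rate_in if enriched else rate_out
        n_sites = rng.poisson(rate * length / 1000.0)
        placed: list[int] = []
        for _ in range(n_sites):
            for _attempt in range(200):
                start = int(rng.integers(0, length - m + 1))
                if all(abs(start - q) >= m for q in placed):
                    placed.append(start)
                    break
        placed.sort()
        for start in placed:
            for j, code in enumerate(motif.consensus):
                base = rng.choice(sorted(IUPAC_CODES[code]))
                seq[start + j] = "ACGT".index(base)
        base_scores = rng.uniform(0.0, 0.6, length)
        for start in placed:
            base_scores[start : start + m] = rng.uniform(0.5, 1.0, m)
        seqs[g] = "".join(_BASES[seq])
        scores[g] = base_scores
        counts[g] = len(placed)
        positions[g] = placed
        lengths[g] = length
    truth = SequenceTruth(
        planted_counts=counts,
        planted_positions=positions,
        lengths=lengths,
        length_module_confound=confound,
    )
    return seqs, scores, truth


# ---------------------------------------------------------------------------
# paired methylation M-values
# ---------------------------------------------------------------------------

@dataclass
class MethylationTruth:
    """Ground truth for planted methylation bias."""

    biased_genes: set[str]
    biased_sites: dict[str, str]
    delta_m: float


def gen_methylation(
    n_patients: int,
    n_sites: int,
    biased_set: set[str],
    delta_m: float,
    seed: int = 0,
    sites_per_gene: int = 2,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, MethylationTruth]:
    """Paired PP/PN M-value matrices with planted hyper-methylated genes.

    Sites are assigned to genes ``G00000``.. in blocks of ``sites_per_gene``.
    For each gene in ``biased_set`` one designated site is shifted by
    ``delta_m`` M units in PP.  Returns ``(m_pp, m_pn, site_to_gene, truth)``
    with matrices sites × patients.
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    rng = np.random.default_rng(seed)
    n_genes = (n_sites + sites_per_gene - 1) // sites_per_gene
    sites = [f"cg{i:06d}" for i in range(n_sites)]
    gene_of = pd.Series(
        [f"G{i // sites_per_gene:05d}" for i in range(n_sites)], index=sites,
        name="gene",
    )
    patients = [f"P{p:03d}" for p in range(n_patients)]

    latent = rng.normal(0.0, 2.0, n_sites)
    m_pn = latent[:, None] + rng.normal(0.0, noise_sd, (n_sites, n_patients))
    m_pp = latent[:, None] + rng.normal(0.0, noise_sd, (n_sites, n_patients))

    biased_sites: dict[str, str] = {}
    for gene in sorted(biased_set):
        site_idx = [i for i, s in enumerate(sites) if gene_of.iloc[i] == gene]
        if not site_idx:
            continue
        chosen = site_idx[0]
        m_pp[chosen] += delta_m
        biased_sites[gene] = sites[chosen]

    truth = MethylationTruth(
        biased_genes=set(biased_sites), biased_sites=biased_sites,
        delta_m=delta_m,
    )
    return (
        pd.DataFrame(m_pp, index=sites, columns=patients),
        pd.DataFrame(m_pn, index=sites, columns=patients),
        gene_of,
        truth,
    )
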