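"""End-to-end composition: spectra + PAM readings -> trait models ->
phenotyping and treatment statistics.

``run_trait_pipeline`` reproduces the full modelling chain on a study:
quality screening (~10% of samples are expected to be defective), a one-off
~20% external hold-out, per-trait split ensembles on the published
range/component configuration, external validation, and prediction of the
passing traits (external R^2 >= 0.55) for the phenotyping plants.
``run_phenotyping`` runs PERMANOVA, PCoA and the PLS-DA grid on the
phenotyping spectra, and ``run_treatment_stats`` the per-trait ANOVA/Tukey
tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indices as vi
from . import phenotyping as ph
from . import traits as tm
from . import treatment_stats as ts
from .spectra import SpectraSet, subset_range, splice_correct, average_replicates
from .synthetic import SyntheticStudy

#: Spectral range analysed throughout (noisy sensor edges discarded).
ANALYSIS_RANGE = (400, 2400)


@dataclass
class TraitPipelineResult:
    outliers: list
    removed_ids: list
    external_ids: list
    models: dict[str, tm.TraitModel]
    summary: pd.DataFrame
    predicted: pd.DataFrame
    skipped: dict[str, str]
    indices: pd.DataFrame


def _trim(sset: SpectraSet) -> SpectraSet:
    return subset_range(sset, *ANALYSIS_RANGE)


def run_trait_pipeline(
    study: SyntheticStudy,
    n_iter: int = 500,
    seed: int = 0,
    external_fraction: float = 0.2,
    r2_threshold: float = 0.55,
    screen_trait: str = "PhiPSII",
    trait_models: dict[str, tuple[int, int, int]] | None = None,
) -> TraitPipelineResult:
    """Run the full spectra-trait modelling chain on a study.

    ``seed`` drives the external hold-out draw and the split ensembles.
    Outlier screening uses the QC flags together with residual/extreme
    screens on ``screen_trait``; flagged samples are dropped before the
    hold-out split.
    """
    if trait_models is None:
        trait_models = tm.DEFAULT_TRAIT_MODELS
    sset = _trim(study.spectra)
    traits_obs = study.truth_traits

    lo, hi, ncomp = trait_models[screen_trait]
    reports = tm.screen_outliers(
        sset, traits_obs[screen_trait], n_components=ncomp,
        model_range=(lo, hi),
    )
    removed = sorted({r.sample_id for r in reports})
    keep_ids = [sid for sid in sset.sample_ids if sid not in removed]

    rng = np.random.default_rng(seed)
    n_ext = int(round(external_fraction * len(keep_ids)))
    ext_ids = sorted(
        np.asarray(keep_ids)[rng.permutation(len(keep_ids))[:n_ext]].tolist()
    )
    model_ids = [sid for sid in keep_ids if sid not in set(ext_ids)]

    models: dict[str, tm.TraitModel] = {}
    for trait, (lo, hi, ncomp) in trait_models.items():
        sub = subset_range(sset, lo, hi)
        X_mod = sub.data.loc[model_ids].to_numpy()
        y_mod = traits_obs.loc[model_ids, trait].to_numpy(dtype=float)
        ens = tm.permutation_ensemble(
            X_mod, y_mod, n_components=ncomp, n_iter=n_iter,
            seed=int(rng.integers(2 ** 31)), wavelengths=sub.wavelengths,
            trait=trait,
        )
        ext = None
        if len(ext_ids) >= 2:
            ext = tm.external_validate(
                ens,
                sub.data.loc[ext_ids].to_numpy(),
                traits_obs.loc[ext_ids, trait].to_numpy(dtype=float),
                model_ids=model_ids, ext_ids=ext_ids,
            )
        models[trait] = tm.TraitModel(
            trait=trait, lo_nm=lo, hi_nm=hi, n_components=ncomp,
            ensemble=ens, external=ext,
        )

    pheno = _trim(study.pheno_spectra)
    predicted, skipped = tm.predict_traits(models, pheno, r2_threshold)
    idx_table = vi.indices_table(pheno)
    return TraitPipelineResult(
        outliers=reports,
        removed_ids=removed,
        external_ids=ext_ids,
        models=models,
        summary=tm.ensemble_summary_table(models),
        predicted=predicted,
        skipped=skipped,
        indices=idx_table,
    )


@dataclass
class PhenotypingReport:
    permanova: ph.PermanovaResult
    pcoa: ph.PCoAResult
    plsda: ph.PLSDAResult


def run_phenotyping(
    study: SyntheticStudy,
    n_permutations: int = 10000,
    plsda_iter: int = 500,
    component_grid: tuple[int, ...] = (2, 4, 6, 8, 10, 13),
    seed: int = 0,
) -> PhenotypingReport:
    """PERMANOVA + PCoA + PLS-DA grid on the phenotyping spectra."""
    pheno = _trim(study.pheno_spectra)
    X = pheno.data.to_numpy()
    groups = pheno.metadata["treatment"].to_numpy()
    perma = ph.permanova(X, groups, n_permutations=n_permutations, seed=seed)
    coords = ph.pcoa(X=X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        grid = ph.plsda_grid(
            X, groups, n_iter=plsda_iter, seed=seed,
            component_grid=component_grid,
        )
    return PhenotypingReport(permanova=perma, pcoa=coords, plsda=grid)


def run_treatment_stats(
    result: TraitPipelineResult,
    study: SyntheticStudy,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA/Tukey tables over predicted traits and vegetation indices."""
    table = pd.concat([result.predicted, result.indices], axis=1)
    return ts.treatment_tables(table, study.pheno_metadata, alpha=alpha)
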