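"""Synthetic coupled PAM-fluorescence / reflectance studies.

The generator emulates the structure of an ozone FACE experiment on date
palm: ~102 paired spectra+PAM samples for spectra-trait model building, and
8 plants per ozone treatment (ambient air AA, moderate MO, elevated EO) for
hyperspectral phenotyping.  Elevated ozone depresses the PSII operating
efficiency (PhiPSII, default -30%) and raises non-photochemical quenching
(qN, default +21%) while leaving dark-adapted Fv/Fm untouched; moderate
ozone is generated like ambient air.

Raw fluorescence yields are drawn so the quenching algebra is internally
consistent: dark-adapted Fv/Fm and Fm are sampled, the light-adapted yields
are obtained by sampling the qN and PhiPSII latents and inverting the
quenching formulas, which guarantees the physical ordering
``0 < F0' <= Fs < Fm' <= Fm`` for every sample.

Reflectance spectra are built as a smooth continuum (logistic red-edge ramp
between a visible floor and a NIR plateau, with SWIR water shoulders) minus
Gaussian absorption features whose depths are affine in (noisy copies of)
the latent traits: a chlorophyll-linked triplet at 625/682/705 nm carries
Fv/Fm, PhiPSII and qN, and water/protein features at 1450/1700/1940 nm add
full-range signal for the ETR/P family.  I.i.d. Gaussian channel noise is
added and reflectance clipped to [0, 1].  A configurable fraction of
spectra receives exactly one planted defect (elevated VIS, splice step at
1001 nm, inverted red edge) with ground-truth flags, matching the failure
modes the quality control in :mod:`phytospec.spectra` screens for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chlf
from .spectra import SpectraSet

TREATMENTS = ("AA", "MO", "EO")

FULL_GRID = np.arange(350, 2501)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the design of the emulated experiment: 102 modelling
    samples, 8 plants per treatment for phenotyping, EO shifting the
    PhiPSII latent by -30% and the qN latent by +21%, actinic PPFD of
    270 umol m-2 s-1, and 10% defective spectra.
    """

    n_model_samples: int = 102
    n_pheno_plants_per_treatment: int = 8
    treatments: tuple[str, ...] = TREATMENTS
    effect_phi_psii: float = -0.30
    effect_qn: float = 0.21
    spectral_noise_sd: float = 0.005
    trait_noise_sd: float = 0.05
    ppfd: float = 270.0
    seed: int = 0
    artifact_fraction: float = 0.10

    def __post_init__(self):
        if self.n_model_samples < 3 or self.n_pheno_plants_per_treatment < 3:
            raise ConfigurationError("sample counts must be >= 3")
        if not self.treatments:
            raise ConfigurationError("empty treatment set")
        for name in ("effect_phi_psii", "effect_qn"):
            e = getattr(self, name)
            if not -1.0 < e < 1.0:
                raise ConfigurationError(f"{name} must lie in (-1, 1)")
        if not 0.0 <= self.artifact_fraction <= 0.5:
            raise ConfigurationError("artifact_fraction must lie in [0, 0.5]")
        if self.spectral_noise_sd < 0 or self.trait_noise_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if not 0.0 <= self.trait_noise_sd <= 1.0:
            raise ConfigurationError("trait_noise_sd is a fraction in [0, 1]")
        if self.ppfd < 0:
            raise ConfigurationError("ppfd must be >= 0")


@dataclass
class SyntheticStudy:
    """One generated study: modelling samples plus phenotyping plants."""

    config: SyntheticConfig
    pam_table: pd.DataFrame
    truth_traits: pd.DataFrame
    spectra: SpectraSet           # modelling samples (with planted defects)
    metadata: pd.DataFrame        # modelling samples
    artifact_flags: pd.Series     # "" for clean, defect name otherwise
    pheno_spectra: SpectraSet     # one spectrum per phenotyping plant
    pheno_truth: pd.DataFrame
    pheno_metadata: pd.DataFrame


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2 ** 31), stream])
    )


def _trunc_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (bounds far from the mean)."""
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def _sample_yields(rng, treatments: np.ndarray, config: SyntheticConfig) -> pd.DataFrame:
    """Draw internally consistent raw PAM yields for the given treatments."""
    n = treatments.shape[0]
    eo = treatments == "EO"
    fvfm = _trunc_normal(rng, 0.78, 0.04, 0.50, 0.87, n)
    fm = _trunc_normal(rng, 0.45, 0.05, 0.20, 0.70, n)
    f0 = fm * (1.0 - fvfm)
    f0p = f0 * _trunc_normal(rng, 0.85, 0.05, 0.65, 1.00, n)
    qn = _trunc_normal(rng, 0.50, 0.05, 0.05, 0.90, n)
    qn = np.where(eo, qn * (1.0 + config.effect_qn), qn)
    qn = np.minimum(qn, 0.97)
    fmp = fm - qn * (fm - f0p)
    fvpfmp = (fmp - f0p) / fmp
    phi = _trunc_normal(rng, 0.52, 0.05, 0.30, 0.75, n)
    phi = np.where(eo, phi * (1.0 + config.effect_phi_psii), phi)
    phi = np.minimum(phi, 0.98 * fvpfmp)
    fs = fmp * (1.0 - phi)
    return pd.DataFrame(
        {
            "F0": f0, "Fm": fm, "Fs": fs,
            "Fm_prime": fmp, "F0_prime": f0p,
            "ppfd": config.ppfd,
        }
    )


def _model_metadata(config: SyntheticConfig) -> pd.DataFrame:
    """Treatment/plot/plant/date labels for the modelling samples."""
    n = config.n_model_samples
    trts = [config.treatments[i % len(config.treatments)] for i in range(n)]
    rows = []
    for i, trt in enumerate(trts):
        plot = f"{trt}{(i // len(config.treatments)) % 3 + 1}"
        rows.append(
            {
                "sample_id": f"M{i + 1:03d}",
                "treatment": trt,
                "plot": plot,
                "plant": f"{plot}-p{i // 9 + 1}",
                "date": f"2019-07-{30 + (i % 4) // 2:02d}",
                "role": "model",
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _pheno_metadata(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for trt in config.treatments:
        for j in range(config.n_pheno_plants_per_treatment):
            rows.append(
                {
                    "sample_id": f"P-{trt}{j + 1:02d}",
                    "treatment": trt,
                    "plot": f"{trt}{j % 3 + 1}",
                    "plant": f"{trt}{j % 3 + 1}-q{j + 1}",
                    "date": "2019-08-02",
                    "role": "phenotype",
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_pam_readings(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the modelling PAM table and its metadata.

    Treatments are cycled so the counts stay balanced; every sample
    satisfies the physical yield ordering, and the EO/AA ratio of mean
    PhiPSII converges to ``1 + effect_phi_psii`` as counts grow.
    """
    meta = _model_metadata(config)
    rng = _rng(config, 0)
    pam = _sample_yields(rng, meta["treatment"].to_numpy(), config)
    pam.index = meta.index
    return pam, meta


# --- spectral forward model -------------------------------------------------

#: (center nm, width nm, base depth, depth span, latent trait, nominal range)
_FEATURES = [
    (625.0, 16.0, 0.015, 0.050, "FvFm", (0.50, 0.87)),
    (682.0, 13.0, 0.015, 0.060, "PhiPSII", (0.10, 0.80)),
    (705.0, 11.0, 0.015, 0.070, "qN", (0.20, 0.90)),
    (1450.0, 45.0, 0.20, 0.10, "PhiPSII", (0.10, 0.80)),
    (1700.0, 60.0, 0.04, 0.04, "qP", (0.00, 1.00)),
    (1940.0, 55.0, 0.30, 0.08, "PhiPSII", (0.10, 0.80)),
]


def _continuum(wl: np.ndarray) -> np.ndarray:
    """Visible floor, logistic red-edge ramp, NIR plateau, green bump."""
    c = 0.10 + 0.35 / (1.0 + np.exp(-(wl - 715.0) / 9.0))
    c = c + 0.03 * np.exp(-0.5 * ((wl - 550.0) / 20.0) ** 2)
    return c


def generate_spectra(
    truth_traits: pd.DataFrame,
    metadata: pd.DataFrame,
    config: SyntheticConfig,
    stream: int = 1,
) -> SpectraSet:
    """Reflectance spectra (350-2500 nm) driven by the latent traits.

    Absorption-feature depths are affine in noisy copies of the trait
    values (noise SD = ``trait_noise_sd`` x nominal trait range), so the
    spectra are informative but imperfect proxies, as in real paired data.
    """
    if not truth_traits.index.equals(metadata.index):
        raise ConfigurationError("traits and metadata sample IDs differ")
    rng = _rng(config, stream)
    wl = FULL_GRID.astype(float)
    n = len(truth_traits)
    refl = np.tile(_continuum(wl), (n, 1))
    for center, width, base, span, trait, (lo, hi) in _FEATURES:
        t = truth_traits[trait].to_numpy(dtype=float)
        # measurement-like decoupling: noise scaled to the realized range
        data_range = float(np.ptp(t)) if n > 1 else (hi - lo)
        noisy = t + rng.normal(0.0, config.trait_noise_sd * data_range, n)
        z = np.clip((noisy - lo) / (hi - lo), 0.0, 1.3)
        depth = base + span * z
        shape = np.exp(-0.5 * ((wl - center) / width) ** 2)
        refl -= np.outer(depth, shape)
    if config.spectral_noise_sd > 0:
        refl += rng.normal(0.0, config.spectral_noise_sd, refl.shape)
    refl = np.clip(refl, 0.0, 1.0)
    data = pd.DataFrame(refl, index=truth_traits.index, columns=FULL_GRID)
    return SpectraSet(data=data, metadata=metadata.copy())


ARTIFACT_TYPES = ("VIS_ELEVATED", "SPLICE_JUMP", "REDEDGE_CONCAVE")


def inject_artifacts(
    sset: SpectraSet,
    config: SyntheticConfig,
    stream: int = 2,
) -> tuple[SpectraSet, pd.Series]:
    """Plant defects into ``round(artifact_fraction * n)`` spectra.

    Each defective spectrum receives exactly one defect, drawn uniformly
    from the three types: +0.15 offset over 400-700 nm, +0.05 step from
    1001 nm onward, or an inverted (mirrored) red edge over 700-750 nm.
    Returns the modified set and the ground-truth flags ("" if clean).
    """
    rng = _rng(config, stream)
    n = len(sset)
    n_bad = int(round(config.artifact_fraction * n))
    flags = pd.Series("", index=sset.data.index, name="artifact")
    data = sset.data.copy()
    if n_bad == 0:
        return SpectraSet(data=data, metadata=sset.metadata.copy()), flags
    wl = sset.wavelengths
    bad_pos = rng.choice(n, size=n_bad, replace=False)
    kinds = rng.integers(0, len(ARTIFACT_TYPES), size=n_bad)
    vis = (wl >= 400) & (wl <= 700)
    swir = wl >= 1001
    rededge = (wl >= 700) & (wl <= 750)
    for pos, kind in zip(bad_pos, kinds):
        sid = data.index[pos]
        row = data.iloc[pos].to_numpy().copy()
        name = ARTIFACT_TYPES[kind]
        if name == "VIS_ELEVATED":
            row[vis] += 0.15
        elif name == "SPLICE_JUMP":
            row[swir] += 0.05
        else:  # mirror the red edge about its chord midline
            seg = row[rededge]
            row[rededge] = seg[0] + seg[-1] - seg
        data.iloc[pos] = np.clip(row, 0.0, 1.0)
        flags.loc[sid] = name
    return SpectraSet(data=data, metadata=sset.metadata.copy()), flags


def generate_study(config: SyntheticConfig = SyntheticConfig()) -> SyntheticStudy:
    """Compose the generators into a full study (modelling + phenotyping)."""
    pam, meta = generate_pam_readings(config)
    truth = chlf.derive_chlf_table(pam)
    clean = generate_spectra(truth, meta, config, stream=1)
    spectra_model, flags = inject_artifacts(clean, config, stream=2)

    pheno_meta = _pheno_metadata(config)
    rng = _rng(config, 3)
    pheno_pam = _sample_yields(rng, pheno_meta["treatment"].to_numpy(), config)
    pheno_pam.index = pheno_meta.index
    pheno_truth = chlf.derive_chlf_table(pheno_pam)
    pheno_spectra = generate_spectra(pheno_truth, pheno_meta, config, stream=4)

    return SyntheticStudy(
        config=config,
        pam_table=pam,
        truth_traits=truth,
        spectra=spectra_model,
        metadata=meta,
        artifact_flags=flags,
        pheno_spectra=pheno_spectra,
        pheno_truth=pheno_truth,
        pheno_metadata=pheno_meta,
    )


def write_study_csv(study: SyntheticStudy, outdir) -> None:
    """Write the spectra/pam/traits/metadata CSV bundle."""
    import json
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = study.config.seed
    study.spectra.to_wide_csv(outdir / "spectra.csv", seed=seed)
    study.pheno_spectra.to_wide_csv(outdir / "pheno_spectra.csv", seed=seed)
    chlf.write_pam_csv(study.pam_table, outdir / "pam.csv")
    chlf.write_traits_csv(study.truth_traits, outdir / "traits.csv")
    meta = pd.concat([study.metadata, study.pheno_metadata])
    meta.to_csv(outdir / "metadata.csv", index_label="sample_id")
    study.artifact_flags.to_csv(outdir / "artifact_flags.csv",
                                index_label="sample_id")
    with open(outdir / "config.json", "w") as fh:
        json.dump(study.config.__dict__, fh, indent=2, default=list)


# --- focused fixtures used by diagnostics tests -----------------------------

def single_band_spectra(
    n: int,
    seed: int,
    center: float = 682.0,
    width: float = 13.0,
    lo_nm: int = 600,
    hi_nm: int = 900,
    noise_sd: float = 0.005,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spectra where a single absorption band carries all the signal.

    Returns ``(wavelengths, X, y)``; useful for checking that VIP puts the
    importance maximum on the informative band.
    """
    rng = np.random.default_rng(seed)
    wl = np.arange(lo_nm, hi_nm + 1, dtype=float)
    y = rng.normal(0.5, 0.12, n)
    shape = np.exp(-0.5 * ((wl - center) / width) ** 2)
    X = _continuum(wl)[None, :] - np.outer(0.02 + 0.08 * y, shape)
    X = X + rng.normal(0.0, noise_sd, X.shape)
    return wl, X, y


def separable_class_spectra(
    n_per_class: int = 8,
    seed: int = 0,
    noise_sd: float = 0.005,
) -> tuple[SpectraSet, np.ndarray]:
    """Three spectrally well-separated classes (a PLS-DA benchmark).

    Each class shifts a different absorption band by several noise SDs, so
    a classifier with adequate components should reach near-perfect
    validation agreement.
    """
    rng = np.random.default_rng(seed)
    wl = FULL_GRID.astype(float)
    centers = {"AA": 560.0, "MO": 682.0, "EO": 1450.0}
    rows, labels, ids = [], [], []
    for cls, center in centers.items():
        shape = np.exp(-0.5 * ((wl - center) / 25.0) ** 2)
        for j in range(n_per_class):
            depth = 0.06 + rng.normal(0.0, 0.005)
            r = _continuum(wl) - depth * shape
            r = r + rng.normal(0.0, noise_sd, r.shape)
            rows.append(np.clip(r, 0.0, 1.0))
            labels.append(cls)
            ids.append(f"{cls}{j + 1:02d}")
    data = pd.DataFrame(np.stack(rows), index=ids, columns=FULL_GRID)
    meta = pd.DataFrame({"treatment": labels}, index=ids)
    return SpectraSet(data=data, metadata=meta), np.asarray(labels)
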