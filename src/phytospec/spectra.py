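"""Leaf reflectance spectra: containers, I/O, preprocessing and quality control.

Spectra are unitless reflectances (leaf radiance over white-reference
radiance) on an integer 1-nm wavelength grid inside 350-2500 nm, the range
of a full-range field spectroradiometer.  Such instruments stitch three
detectors; the module knows the two splice boundaries (1000/1001 and
1800/1801 nm) and can remove step discontinuities there.

Quality control targets the three operational failure modes seen in leaf-clip
measurements: elevated reflectance across the visible range (bad white
reference), splice steps (misaligned detectors), and an inverted red-edge
shape (probe slip during collection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Detector splice boundaries: last wavelength of the left-hand detector.
SPLICE_BOUNDARIES = (1000, 1800)


class SpectraError(ValueError):
    pass


@dataclass
class Spectrum:
    """A single reflectance spectrum on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_id: str = ""

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise SpectraError("wavelengths and reflectance lengths differ")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise SpectraError("non-finite reflectance values")

    def value_at(self, nm: float) -> float:
        idx = np.nonzero(self.wavelengths == nm)[0]
        if idx.size == 0:
            raise SpectraError(f"wavelength {nm} nm not on the grid")
        return float(self.reflectance[idx[0]])


@dataclass
class SpectraSet:
    """Samples x wavelengths reflectance matrix with sample metadata.

    ``data`` is indexed by sample_id with integer-nm columns; ``metadata``
    (treatment / plot / plant / date ...) shares the same index.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise SpectraError("duplicated sample_id in SpectraSet")
        self.data.columns = self.data.columns.astype(int)
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=self.data.index)
        else:
            self.metadata = self.metadata.loc[self.data.index]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.data.columns.to_numpy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def spectrum(self, sample_id: str) -> Spectrum:
        return Spectrum(
            wavelengths=self.wavelengths.astype(float),
            reflectance=self.data.loc[sample_id].to_numpy(),
            sample_id=str(sample_id),
        )

    def __iter__(self):
        for sid in self.data.index:
            yield self.spectrum(sid)

    def to_wide_csv(self, path, seed: int | None = None) -> None:
        """Write the wide spectra.csv layout (``sample_id,w350,...,w2500``)."""
        out = self.data.copy()
        out.columns = [f"w{c}" for c in out.columns]
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            out.to_csv(fh, index_label="sample_id")

    @classmethod
    def from_wide_csv(cls, path, metadata: pd.DataFrame | None = None) -> "SpectraSet":
        df = pd.read_csv(path, index_col="sample_id", comment="#")
        df.columns = [int(str(c).lstrip("w")) for c in df.columns]
        return cls(data=df, metadata=metadata if metadata is not None else pd.DataFrame())


@dataclass(frozen=True)
class QCThresholds:
    """Cutoffs for the three defect detectors (config-exposed)."""

    vis_mean_max: float = 0.15
    splice_step: float = 0.01
    vis_range: tuple[int, int] = (400, 700)
    rededge_range: tuple[int, int] = (700, 750)
    rededge_slope_range: tuple[int, int] = (735, 750)
    fit_window: int = 50


@dataclass
class QCReport:
    """Per-spectrum defect flags with the metrics backing each decision."""

    sample_id: str
    flags: list[str]
    metrics: dict

    @property
    def passed(self) -> bool:
        return not self.flags


def _segment(s: Spectrum, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    m = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    return s.wavelengths[m], s.reflectance[m]


def _splice_step_estimate(s: Spectrum, boundary: int, window: int = 50) -> float:
    """Discontinuity (right minus left) at a detector splice.

    The reflectance over ``window`` nm on each side of the boundary is
    fitted by a cubic trend plus a step indicator for the right-hand
    detector; the least-squares step coefficient is the estimate.  A smooth
    (locally cubic) spectrum therefore yields ~0 while a rigid step is
    recovered in full, and channel noise is averaged down.
    """
    wl, r = _segment(s, boundary - window + 1, boundary + window)
    right = wl > boundary
    if right.sum() < 5 or (~right).sum() < 5:
        raise SpectraError(
            f"grid does not cover the splice neighbourhood at {boundary} nm"
        )
    x = (wl - boundary) / window
    design = np.column_stack(
        [np.ones_like(x), x, x ** 2, x ** 3, right.astype(float)]
    )
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    return float(coef[4])


def splice_correct(
    s: Spectrum,
    boundaries: tuple[int, ...] = SPLICE_BOUNDARIES,
    window: int = 50,
) -> Spectrum:
    """Remove step discontinuities at the detector splices.

    The first (VNIR) segment is the anchor; each segment to the right is
    rigidly shifted so the spectrum is continuous at every boundary.  The
    operation is idempotent up to numerical noise.
    """
    r = s.reflectance.copy()
    for b in sorted(boundaries):
        step = _splice_step_estimate(
            Spectrum(s.wavelengths, r, s.sample_id), b, window
        )
        r = np.where(s.wavelengths > b, r - step, r)
    return replace(s, reflectance=r)


def resample_to_grid(s: Spectrum, lo_nm: int, hi_nm: int) -> Spectrum:
    """Linear interpolation onto the inclusive integer 1-nm grid [lo, hi]."""
    if lo_nm > hi_nm:
        raise SpectraError("lo_nm > hi_nm")
    if lo_nm < s.wavelengths[0] or hi_nm > s.wavelengths[-1]:
        raise SpectraError(
            f"requested range {lo_nm}-{hi_nm} nm extends beyond the measured "
            f"range {s.wavelengths[0]:.0f}-{s.wavelengths[-1]:.0f} nm"
        )
    grid = np.arange(lo_nm, hi_nm + 1, dtype=float)
    return Spectrum(
        wavelengths=grid,
        reflectance=np.interp(grid, s.wavelengths, s.reflectance),
        sample_id=s.sample_id,
    )


def average_replicates(replicates: list[Spectrum]) -> SpectraSet:
    """Per-wavelength mean of replicate spectra grouped by sample_id.

    Leaf-clip protocols collect several spots per leaf; the leaf spectrum is
    their arithmetic mean.  All replicates must share one grid.  The
    replicate count is recorded in the metadata (``n_replicates``).
    """
    if not replicates:
        raise SpectraError("no replicate spectra given")
    grid = replicates[0].wavelengths
    groups: dict[str, list[np.ndarray]] = {}
    for s in replicates:
        if s.wavelengths.shape != grid.shape or np.any(s.wavelengths != grid):
            raise SpectraError("replicates are on mixed wavelength grids")
        groups.setdefault(s.sample_id, []).append(s.reflectance)
    rows = {sid: np.mean(np.stack(rs), axis=0) for sid, rs in groups.items()}
    data = pd.DataFrame.from_dict(rows, orient="index", columns=grid.astype(int))
    meta = pd.DataFrame(
        {"n_replicates": {sid: len(rs) for sid, rs in groups.items()}}
    )
    return SpectraSet(data=data, metadata=meta)


def subset_range(sset: SpectraSet, lo_nm: int, hi_nm: int) -> SpectraSet:
    """Inclusive wavelength slice of a SpectraSet; metadata preserved."""
    if lo_nm > hi_nm:
        raise SpectraError("lo_nm > hi_nm")
    cols = [c for c in sset.data.columns if lo_nm <= c <= hi_nm]
    if not cols:
        raise SpectraError(f"no wavelengths in {lo_nm}-{hi_nm} nm")
    return SpectraSet(data=sset.data[cols].copy(), metadata=sset.metadata.copy())


def qc_flags(s: Spectrum, thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Screen one spectrum for the three operational defects.

    * ``VIS_ELEVATED``  - mean reflectance over the visible range above
      ``vis_mean_max`` (default 0.15), the signature of a bad white
      reference.
    * ``SPLICE_JUMP``   - discontinuity at either detector boundary larger
      than ``splice_step`` (default 0.01), estimated by two-sided local
      linear fits (noise-robust version of the boundary first difference).
    * ``REDEDGE_CONCAVE`` - inverted red-edge shape: the quadratic curvature
      fitted over 700-750 nm is positive while the fitted slope over
      735-750 nm is negative (a healthy red edge rises and flattens, i.e.
      the opposite signs).
    """
    t = thresholds
    flags: list[str] = []
    wl_vis, r_vis = _segment(s, *t.vis_range)
    vis_mean = float(np.mean(r_vis))
    if vis_mean > t.vis_mean_max:
        flags.append("VIS_ELEVATED")

    steps = {}
    for b in SPLICE_BOUNDARIES:
        steps[b] = _splice_step_estimate(s, b, t.fit_window)
    if any(abs(v) > t.splice_step for v in steps.values()):
        flags.append("SPLICE_JUMP")

    wl_re, r_re = _segment(s, *t.rededge_range)
    c2 = np.polyfit(wl_re - wl_re.mean(), r_re, 2)[0]
    curvature = 2.0 * float(c2)  # second derivative of the fitted parabola
    wl_sl, r_sl = _segment(s, *t.rededge_slope_range)
    slope = float(np.polyfit(wl_sl - wl_sl.mean(), r_sl, 1)[0])
    if curvature > 0 and slope < 0:
        flags.append("REDEDGE_CONCAVE")

    return QCReport(
        sample_id=s.sample_id,
        flags=flags,
        metrics={
            "vis_mean": vis_mean,
            "splice_step_1000": steps[1000],
            "splice_step_1800": steps[1800],
            "rededge_curvature": curvature,
            "rededge_slope": slope,
        },
    )


def qc_table(sset: SpectraSet, thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Run :func:`qc_flags` over a set; one row per sample."""
    rows = []
    for s in sset:
        rep = qc_flags(s, thresholds)
        rows.append(
            {"sample_id": rep.sample_id, "flags": ";".join(rep.flags),
             "passed": rep.passed, **rep.metrics}
        )
    return pd.DataFrame(rows).set_index("sample_id")
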