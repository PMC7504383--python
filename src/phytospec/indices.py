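"""Narrow-band vegetation indices.

Three indices probe the photochemical system, senescence and chlorophyll
content from single 1-nm reflectance bands:

* ``PRI  = (R531 - R570) / (R531 + R570)`` (photochemical reflectance index),
* ``PSRI = (R678 - R500) / R750`` (plant senescence reflectance index),
* ``CI   = (R750 - R705) / (R750 + R705)`` (red-edge chlorophyll index),

with the scaled variants ``sPRI = (PRI + 1)/2`` and ``sPSRI = (PSRI + 1)/2``
mapping into non-negative ranges.  Reflectance is read at the exact integer
wavelength, not a band average.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .spectra import Spectrum, SpectraSet, SpectraError


@dataclass(frozen=True)
class IndexSet:
    pri: float
    spri: float
    psri: float
    spsri: float
    ci: float

    def as_dict(self) -> dict:
        return asdict(self)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        raise SpectraError(f"zero denominator computing {name}")
    return num / den


def compute_indices(s: Spectrum) -> IndexSet:
    """Compute PRI, sPRI, PSRI, sPSRI and CI from one spectrum.

    The spectrum must cover 500-750 nm on a 1-nm grid; a missing wavelength
    or zero denominator raises :class:`~phytospec.spectra.SpectraError`.
    """
    r = {nm: s.value_at(nm) for nm in (500, 531, 570, 678, 705, 750)}
    pri = _ratio(r[531] - r[570], r[531] + r[570], "PRI")
    psri = _ratio(r[678] - r[500], r[750], "PSRI")
    ci = _ratio(r[750] - r[705], r[750] + r[705], "CI")
    return IndexSet(
        pri=pri, spri=(pri + 1.0) / 2.0,
        psri=psri, spsri=(psri + 1.0) / 2.0,
        ci=ci,
    )


def indices_table(sset: SpectraSet) -> pd.DataFrame:
    """Per-sample index table for a SpectraSet."""
    rows = {s.sample_id: compute_indices(s).as_dict() for s in sset}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
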