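"""Pulse-amplitude-modulation (PAM) chlorophyll *a* fluorescence parameters.

Saturation-pulse quenching analysis yields five raw fluorescence levels per
leaf: the minimum and maximum yield on a dark-adapted leaf (``F0``, ``Fm``)
and the steady-state, maximum and minimum yields under actinic light
(``Fs``, ``Fm_prime``, ``F0_prime``).  From these the standard set of
fifteen parameters is derived:

======== =======================================================
Fv/Fm    maximum quantum efficiency of PSII, (Fm - F0)/Fm
PhiPSII  PSII operating efficiency, (Fm' - Fs)/Fm'
Fv'/Fm'  maximum PSII efficiency in the light, (Fm' - F0')/Fm'
ETR      electron transport rate, PhiPSII * PPFD * 0.5 * 0.84
qP       photochemical quenching, (Fm' - Fs)/(Fm' - F0')
qN       non-photochemical quenching, (Fm - Fm')/(Fm - F0')
NPQ      non-photochemical quenching, (Fm - Fm')/Fm'
qL       fraction of open PSII centres, qP * F0'/Fs
P        light absorbed by PSII used in photochemistry, (Fv'/Fm') * qP
D        light absorbed by PSII dissipated thermally, 1 - Fv'/Fm'
======== =======================================================

``P`` equals ``PhiPSII`` algebraically and ``P + D <= 1``; both identities
are preserved to machine precision and exercised by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

#: Partitioning of absorbed quanta between PSII and PSI.
ETR_PARTITION = 0.5
#: Absorption coefficient of an average leaf.
ETR_ABSORPTANCE = 0.84
#: Actinic light level (umol m-2 s-1) used when no per-sample PPFD is given.
DEFAULT_PPFD = 270.0

#: Raw yield columns expected in a PAM table.
PAM_COLUMNS = ["F0", "Fm", "Fs", "Fm_prime", "F0_prime", "ppfd"]

#: The fifteen derived-trait columns, raw yields first.
TRAIT_COLUMNS = [
    "F0", "Fm", "Fs", "Fm_prime", "F0_prime",
    "FvFm", "PhiPSII", "FvpFmp", "ETR",
    "qP", "qN", "NPQ", "qL", "P", "D",
]


class ChlFValidationError(ValueError):
    """A PAM reading violates the physical ordering of fluorescence yields."""


@dataclass(frozen=True)
class PAMReading:
    """One saturation-pulse measurement (instrument-normalised yields)."""

    F0: float
    Fm: float
    Fs: float
    Fm_prime: float
    F0_prime: float
    ppfd: float = DEFAULT_PPFD


@dataclass(frozen=True)
class ChlFTraits:
    """Raw yields plus the fifteen derived quenching parameters."""

    F0: float
    Fm: float
    Fs: float
    Fm_prime: float
    F0_prime: float
    FvFm: float
    PhiPSII: float
    FvpFmp: float
    ETR: float
    qP: float
    qN: float
    NPQ: float
    qL: float
    P: float
    D: float

    def as_dict(self) -> dict:
        return asdict(self)


def validate_reading(reading: PAMReading) -> list[str]:
    """Return the list of violated yield constraints (empty if valid).

    A physically admissible reading satisfies ``0 < F0 < Fm``,
    ``0 < F0' <= Fs < Fm' <= Fm`` and ``ppfd >= 0``.
    """
    v: list[str] = []
    for name in ("F0", "Fm", "Fs", "Fm_prime", "F0_prime"):
        value = getattr(reading, name)
        if not np.isfinite(value) or value <= 0:
            v.append(f"{name} <= 0")
    if reading.F0 >= reading.Fm:
        v.append("F0 >= Fm")
    if reading.F0_prime > reading.Fs:
        v.append("F0_prime > Fs")
    if reading.Fs >= reading.Fm_prime:
        v.append("Fs >= Fm_prime")
    if reading.Fm_prime > reading.Fm:
        v.append("Fm_prime > Fm")
    if not np.isfinite(reading.ppfd) or reading.ppfd < 0:
        v.append("ppfd < 0")
    return v


def derive_chlf(reading: PAMReading) -> ChlFTraits:
    """Derive all fifteen ChlF parameters from one valid PAM reading.

    Raises
    ------
    ChlFValidationError
        If the reading violates the yield ordering; the message names every
        violated inequality.
    """
    violations = validate_reading(reading)
    if violations:
        raise ChlFValidationError(
            "invalid PAM reading: " + "; ".join(violations)
        )
    F0, Fm = reading.F0, reading.Fm
    Fs, Fmp, F0p = reading.Fs, reading.Fm_prime, reading.F0_prime
    fvfm = (Fm - F0) / Fm
    phi = (Fmp - Fs) / Fmp
    fvpfmp = (Fmp - F0p) / Fmp
    etr = phi * reading.ppfd * ETR_PARTITION * ETR_ABSORPTANCE
    qp = (Fmp - Fs) / (Fmp - F0p)
    qn = (Fm - Fmp) / (Fm - F0p)
    npq = (Fm - Fmp) / Fmp
    ql = qp * (F0p / Fs)
    p = fvpfmp * qp
    d = 1.0 - fvpfmp
    return ChlFTraits(
        F0=F0, Fm=Fm, Fs=Fs, Fm_prime=Fmp, F0_prime=F0p,
        FvFm=fvfm, PhiPSII=phi, FvpFmp=fvpfmp, ETR=etr,
        qP=qp, qN=qn, NPQ=npq, qL=ql, P=p, D=d,
    )


def derive_chlf_table(pam: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`derive_chlf` over a PAM table.

    ``pam`` needs columns ``F0, Fm, Fs, Fm_prime, F0_prime`` and optionally
    ``ppfd`` (default :data:`DEFAULT_PPFD`).  The index is preserved.  The
    whole table is validated first; a single error reports every offending
    sample.
    """
    required = [c for c in PAM_COLUMNS if c != "ppfd"]
    missing = [c for c in required if c not in pam.columns]
    if missing:
        raise KeyError(f"PAM table missing columns: {missing}")
    ppfd = pam["ppfd"] if "ppfd" in pam.columns else pd.Series(
        DEFAULT_PPFD, index=pam.index
    )
    bad_ids = []
    for idx, row in pam.iterrows():
        r = PAMReading(
            F0=row["F0"], Fm=row["Fm"], Fs=row["Fs"],
            Fm_prime=row["Fm_prime"], F0_prime=row["F0_prime"],
            ppfd=float(ppfd.loc[idx]),
        )
        if validate_reading(r):
            bad_ids.append(idx)
    if bad_ids:
        raise ChlFValidationError(
            f"invalid PAM readings for samples: {bad_ids}"
        )
    F0, Fm = pam["F0"].to_numpy(), pam["Fm"].to_numpy()
    Fs = pam["Fs"].to_numpy()
    Fmp, F0p = pam["Fm_prime"].to_numpy(), pam["F0_prime"].to_numpy()
    pp = ppfd.to_numpy(dtype=float)
    phi = (Fmp - Fs) / Fmp
    fvpfmp = (Fmp - F0p) / Fmp
    qp = (Fmp - Fs) / (Fmp - F0p)
    out = pd.DataFrame(
        {
            "F0": F0, "Fm": Fm, "Fs": Fs, "Fm_prime": Fmp, "F0_prime": F0p,
            "FvFm": (Fm - F0) / Fm,
            "PhiPSII": phi,
            "FvpFmp": fvpfmp,
            "ETR": phi * pp * ETR_PARTITION * ETR_ABSORPTANCE,
            "qP": qp,
            "qN": (Fm - Fmp) / (Fm - F0p),
            "NPQ": (Fm - Fmp) / Fmp,
            "qL": qp * (F0p / Fs),
            "P": fvpfmp * qp,
            "D": 1.0 - fvpfmp,
        },
        index=pam.index,
    )
    return out[TRAIT_COLUMNS]


def read_pam_csv(path) -> pd.DataFrame:
    """Read a pam.csv table (sample_id index, raw yield columns)."""
    return pd.read_csv(path, index_col="sample_id", comment="#")


def write_pam_csv(pam: pd.DataFrame, path) -> None:
    pam.to_csv(path, index_label="sample_id")


def write_traits_csv(traits: pd.DataFrame, path) -> None:
    """Write a traits.csv table with all fifteen parameter columns."""
    traits[TRAIT_COLUMNS].to_csv(path, index_label="sample_id")


def read_traits_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id", comment="#")
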