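"""NMR-derived per-residue mobility metrics.

Three quantities are computed here:

* amide-proton secondary chemical shifts, dd1HN = d_obs - d_randomcoil
  (negative values report lengthened HN...OC hydrogen bonds, i.e.
  locally destabilized helix);
* the 15N CSA/dipolar cross-correlated transverse relaxation rate eta
  from the reference/attenuated peak-intensity ratio of an interleaved
  TROSY-type experiment, eta = ln(I_ref/I_att) / (2 Delta);
* the effective rotational correlation time tau_R obtained by
  inverting the rigid-rotor forward model

      eta(tau) = C * P2(cos theta) * (4 J(0) + 3 J(omega_N)),
      J(w) = (2/5) tau / (1 + w^2 tau^2),

  where C is the product of the 1H-15N dipolar coupling constant and
  the 15N CSA term at the given field, and theta the angle between the
  CSA principal axis and the NH bond.  The forward map is strictly
  increasing in tau, so the inversion is a bracketed root find.

Magnitudes of the gyromagnetic ratio of 15N and of the CSA are used in
C, so eta > 0 for tau > 0 regardless of sign conventions.  Externally
computed helicity (HSP) and order-parameter (S2) tables are ingested
for joint reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .helix_geometry import HelixSegment
from .structure_io import IntensityRecord, ShiftRecord

__all__ = [
    "RANDOM_COIL_HN",
    "RelaxationParams",
    "TauProfile",
    "EtaResult",
    "secondary_shift_hn",
    "eta_from_intensities",
    "forward_eta",
    "tau_from_eta",
    "tau_profile_from_intensities",
    "segment_average_tau",
    "read_hsp_s2_table",
]

# physical constants (SI)
_MU0 = 4e-7 * math.pi
_HBAR = 1.054571817e-34
_GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1
_GAMMA_N = 2.7126189e7  # magnitude; 15N gamma is negative

#: random-coil 1HN chemical shifts, ppm (Wishart et al., J Biomol NMR 5,
#: 67-81, 1995).  Proline has no amide proton -> NaN.
RANDOM_COIL_HN: dict[str, float] = {
    "ALA": 8.24, "ARG": 8.23, "ASN": 8.40, "ASP": 8.34, "CYS": 8.32,
    "GLN": 8.32, "GLU": 8.42, "GLY": 8.33, "HIS": 8.42, "ILE": 8.00,
    "LEU": 8.16, "LYS": 8.29, "MET": 8.28, "PHE": 8.30, "PRO": float("nan"),
    "SER": 8.31, "THR": 8.15, "TRP": 8.25, "TYR": 8.12, "VAL": 8.03,
}


@dataclass(frozen=True)
class RelaxationParams:
    """Constants of the cross-correlated relaxation experiment.

    Defaults: 600 MHz spectrometer, 15N CSA -170 ppm, r_NH = 1.02 A,
    17 deg between the CSA axis and the NH vector, relaxation period
    Delta = 10.8 ms.
    """

    frequency_mhz: float = 600.0
    csa_ppm: float = -170.0
    r_nh_angstrom: float = 1.02
    theta_deg: float = 17.0
    delta_s: float = 0.0108

    def __post_init__(self) -> None:
        if self.frequency_mhz <= 0 or self.r_nh_angstrom <= 0 or self.delta_s <= 0:
            raise ValueError("frequency, bond length and Delta must be positive")
        if self.csa_ppm == 0:
            raise ValueError("CSA must be nonzero")

    @property
    def b0_tesla(self) -> float:
        return 2.0 * math.pi * self.frequency_mhz * 1e6 / _GAMMA_H

    @property
    def omega_n(self) -> float:
        """15N Larmor frequency magnitude, rad/s."""
        return _GAMMA_N * self.b0_tesla

    @property
    def prefactor(self) -> float:
        """C = dipolar coupling x CSA term, s^-2 (magnitudes)."""
        r = self.r_nh_angstrom * 1e-10
        dd = (_MU0 / (4.0 * math.pi)) * _HBAR * _GAMMA_H * _GAMMA_N / r**3
        csa = _GAMMA_N * self.b0_tesla * abs(self.csa_ppm) * 1e-6 / 3.0
        return dd * csa

    @property
    def p2_cos_theta(self) -> float:
        c = math.cos(math.radians(self.theta_deg))
        return 0.5 * (3.0 * c * c - 1.0)


def _spectral_density(omega: float, tau_s: float) -> float:
    return 0.4 * tau_s / (1.0 + (omega * tau_s) ** 2)


def forward_eta(tau_ns: float, params: RelaxationParams = RelaxationParams()) -> float:
    """Cross-correlation rate eta (s^-1) for a rigid rotor of given tau_R."""
    if tau_ns <= 0:
        raise ValueError("tau must be positive")
    tau = tau_ns * 1e-9
    j = 4.0 * _spectral_density(0.0, tau) + 3.0 * _spectral_density(params.omega_n, tau)
    return params.prefactor * params.p2_cos_theta * j


@dataclass(frozen=True)
class EtaResult:
    eta: float  # s^-1
    sigma: float  # s^-1, first-order propagated
    reason: str | None = None  # set when undefined

    @property
    def defined(self) -> bool:
        return self.reason is None


def eta_from_intensities(
    rec: IntensityRecord, delta: float = RelaxationParams().delta_s
) -> EtaResult:
    """eta = ln(I_ref / I_att) / (2 Delta), with noise propagation.

    sigma_eta = sqrt((s/I_ref)^2 + (s/I_att)^2) / (2 Delta).  Records
    with non-positive attenuated intensity yield an undefined marker.
    """
    if rec.i_att <= 0:
        return EtaResult(float("nan"), float("nan"), reason="non-positive attenuated intensity")
    eta = math.log(rec.i_ref / rec.i_att) / (2.0 * delta)
    sigma = (
        math.hypot(rec.sigma_noise / rec.i_ref, rec.sigma_noise / rec.i_att)
        / (2.0 * delta)
    )
    return EtaResult(eta, sigma)


TAU_MAX_NS = 200.0


def tau_from_eta(
    eta: float,
    params: RelaxationParams = RelaxationParams(),
    sigma_eta: float = 0.0,
    tau_max_ns: float = TAU_MAX_NS,
) -> tuple[float, float]:
    """Invert the forward model: tau_R (ns) and its uncertainty.

    The forward map eta(tau) is strictly monotone increasing, so a
    bracketed Brent root find on (0, tau_max] converges; tolerance
    1e-4 ns.  The uncertainty is sigma_eta / |d eta / d tau|.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    eta_hi = forward_eta(tau_max_ns, params)
    if eta > eta_hi:
        raise ValueError(
            f"eta = {eta:.3g} s^-1 exceeds the rate attainable for tau <= "
            f"{tau_max_ns} ns ({eta_hi:.3g} s^-1)"
        )
    tau = brentq(
        lambda t: forward_eta(t, params) - eta, 1e-6, tau_max_ns, xtol=1e-4
    )
    h = max(1e-4, 1e-4 * tau)
    deriv = (forward_eta(tau + h, params) - forward_eta(max(tau - h, 1e-6), params)) / (
        tau + h - max(tau - h, 1e-6)
    )
    sigma_tau = sigma_eta / abs(deriv) if sigma_eta else 0.0
    return float(tau), float(sigma_tau)


@dataclass
class TauProfile:
    """residue_number -> (tau_R ns, uncertainty ns); NaN where undefined."""

    table: pd.DataFrame  # columns: residue_number, tau_ns, sigma_ns, reason

    def __getitem__(self, residue: int) -> float:
        row = self.table[self.table.residue_number == residue]
        if row.empty:
            raise KeyError(residue)
        return float(row.tau_ns.iloc[0])

    def defined(self) -> pd.DataFrame:
        return self.table[np.isfinite(self.table.tau_ns)]


def tau_profile_from_intensities(
    records: Sequence[IntensityRecord],
    params: RelaxationParams = RelaxationParams(),
) -> TauProfile:
    """Per-residue tau_R from intensity pairs; failures become markers."""
    rows = []
    for rec in records:
        res = eta_from_intensities(rec, params.delta_s)
        if not res.defined:
            rows.append(
                {"residue_number": rec.residue_number, "tau_ns": float("nan"),
                 "sigma_ns": float("nan"), "reason": res.reason}
            )
            continue
        try:
            tau, sigma = tau_from_eta(res.eta, params, res.sigma)
            rows.append(
                {"residue_number": rec.residue_number, "tau_ns": tau,
                 "sigma_ns": sigma, "reason": None}
            )
        except ValueError as exc:
            rows.append(
                {"residue_number": rec.residue_number, "tau_ns": float("nan"),
                 "sigma_ns": float("nan"), "reason": str(exc)}
            )
    return TauProfile(pd.DataFrame(rows))


def segment_average_tau(
    profile: TauProfile, segment: HelixSegment
) -> tuple[float, int]:
    """Unweighted mean tau_R over the segment's defined residues.

    Returns (mean ns, count).  (NaN, 0) when no residue is defined.
    """
    sub = profile.defined()
    sub = sub[
        (sub.residue_number >= segment.first_residue)
        & (sub.residue_number <= segment.last_residue)
    ]
    if sub.empty:
        return float("nan"), 0
    return float(sub.tau_ns.mean()), int(len(sub))


def secondary_shift_hn(
    shifts: Sequence[ShiftRecord],
    residue_names: Mapping[int, str] | None = None,
    random_coil: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """dd1HN = observed - random-coil amide-proton shift, per residue.

    Residue types come from the shift records themselves or from
    ``residue_names``; a type absent from the random-coil table is an
    error.  Residues without an HN shift (or proline) are NaN with the
    ``helix_destabilized`` flag unset.  The flag marks negative dd1HN,
    i.e. lengthened HN...OC hydrogen bonds.
    """
    rc = RANDOM_COIL_HN if random_coil is None else random_coil
    rows = []
    hn = [r for r in shifts if r.atom in ("HN", "H")]
    for rec in hn:
        name = rec.residue_name or (residue_names or {}).get(rec.residue_number)
        if name is None:
            raise ValueError(
                f"residue {rec.residue_number}: residue type unknown "
                "(provide residue_names or a residue_name column)"
            )
        if name not in rc:
            raise KeyError(f"residue type {name} absent from the random-coil table")
        base = rc[name]
        dd = rec.shift - base if np.isfinite(base) else float("nan")
        rows.append(
            {
                "residue_number": rec.residue_number,
                "residue_name": name,
                "dd_hn_ppm": dd,
                "helix_destabilized": bool(np.isfinite(dd) and dd < 0),
            }
        )
    return pd.DataFrame(rows).sort_values("residue_number").reset_index(drop=True)


def read_hsp_s2_table(path) -> pd.DataFrame:
    """Ingest an externally computed per-residue (HSP, S2) table.

    TSV columns: ``residue_number``, ``hsp``, ``s2``; both values must
    lie in [0, 1].  An empty file yields an empty frame (the caller may
    treat that as a warning); out-of-range values are an error.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["residue_number", "hsp", "s2"])
    if df.empty:
        return pd.DataFrame(columns=["residue_number", "hsp", "s2"])
    required = {"residue_number", "hsp", "s2"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: HSP/S2 table must have columns {sorted(required)}")
    for col in ("hsp", "s2"):
        bad = df[(df[col] < 0) | (df[col] > 1)]
        if not bad.empty:
            raise ValueError(
                f"{path}: {col} out of [0, 1] for residues "
                f"{bad.residue_number.tolist()}"
            )
    return df[["residue_number", "hsp", "s2"]].astype({"residue_number": int})
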