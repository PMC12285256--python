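"""Protease activity quantification from plate-reader data.

Covers the bench arithmetic of the screen's validation stage: kinetic
slopes of fluorogenic substrate turnover, linear standard curves (released
Nma fluorophore for FRET substrates; Bradford for total protein), specific
activity (fluorescence increase per minute per mg supernatant protein),
relative activity against a reference strain, and 19-amino-acid P1
substrate-specificity profiles (all proteinogenic residues except Cys,
whose FRET substrate is not part of the panel).

Units: one IU is 1 umol of released product per minute; IU/mL refers to
the volume of culture supernatant in the reaction (50 uL by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "AMINO_ACIDS_19",
    "StandardCurve",
    "ActivityRecord",
    "SpecificityProfile",
    "kinetic_slope",
    "fit_standard_curve",
    "specific_activity",
    "relative_to_reference",
    "iu_per_ml",
    "specificity_profile",
]

#: P1 residues of the FRET substrate panel: the 20 standard amino acids minus Cys
AMINO_ACIDS_19 = (
    "Ala", "Arg", "Asn", "Asp", "Gln", "Glu", "Gly", "His", "Ile", "Leu",
    "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

#: default amount ranges of the two standard curves, in curve units
STANDARD_RANGES = {
    "nma_fluorescence": (16e-3, 1.0),  # nmol Nma equivalent (16 pmol - 1 nmol)
    "bradford_protein": (0.0, 0.25),  # mg/mL bovine gamma globulin
}


@dataclass(frozen=True)
class StandardCurve:
    """A linear signal-vs-amount calibration."""

    kind: str  # "nma_fluorescence" | "bradford_protein"
    slope: float  # signal per amount unit
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    def amount_from_signal(self, signal):
        """Inverse prediction: amount producing the observed signal."""
        return (np.asarray(signal, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class ActivityRecord:
    """One strain's supernatant activity measurement."""

    strain_id: str
    dF_per_min: float
    protein_mg: float
    specific_activity: float
    relative_pct: float | None = None
    iu_per_ml: float | None = None


@dataclass(frozen=True)
class SpecificityProfile:
    """P1-residue substrate specificity, scaled to the best residue = 100%."""

    amino_acids: tuple[str, ...]
    activities_iu_per_ml: np.ndarray
    relative_pct: np.ndarray


def kinetic_slope(times_min, fluorescence) -> float:
    """Fluorescence increase per minute: OLS slope over the kinetic read.

    Uses the full series; trim the input to the linear region first if the
    reaction saturates within the read window.
    """
    t = np.asarray(list(times_min), dtype=float)
    f = np.asarray(list(fluorescence), dtype=float)
    if t.shape != f.shape:
        raise ValueError("times and fluorescence must have equal length")
    if len(t) < 3:
        raise ValueError(f"need at least 3 points for a slope, got {len(t)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(stats.linregress(t, f).slope)


def fit_standard_curve(amounts, signals, kind: str) -> StandardCurve:
    """Fit a linear standard curve and record its valid amount range."""
    if kind not in STANDARD_RANGES:
        raise ValueError(f"unknown standard-curve kind {kind!r}")
    x = np.asarray(list(amounts), dtype=float)
    y = np.asarray(list(signals), dtype=float)
    if len(x) < 3:
        raise ValueError(f"need at least 3 standards, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("standards are all at the same amount")
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    return StandardCurve(
        kind=kind,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        valid_range=(float(x.min()), float(x.max())),
    )


def specific_activity(dF_per_min: float, protein_mg: float) -> float:
    """Fluorescence increase per minute per mg of supernatant protein."""
    if protein_mg <= 0:
        raise ValueError(f"protein mass must be positive, got {protein_mg}")
    return dF_per_min / protein_mg


def relative_to_reference(
    records: list[ActivityRecord], reference_strain: str
) -> list[ActivityRecord]:
    """Express every strain's specific activity as % of a reference strain.

    The reference strain itself gets exactly 100%.
    """
    ref = [r for r in records if r.strain_id == reference_strain]
    if not ref:
        raise ValueError(f"reference strain {reference_strain!r} not in records")
    ref_activity = ref[0].specific_activity
    if ref_activity <= 0:
        raise ValueError("reference strain has non-positive specific activity")
    return [
        replace(r, relative_pct=100.0 * r.specific_activity / ref_activity)
        for r in records
    ]


def iu_per_ml(
    dF_per_min: float,
    nma_curve: StandardCurve,
    supernatant_ul: float = 50.0,
) -> float:
    """Convert a fluorescence slope to enzymatic units per mL supernatant.

    The Nma standard curve converts fluorescence to nmol of released
    product; 1 IU = 1 umol product/min. Doubling the supernatant volume at
    a fixed product rate halves IU/mL.
    """
    if nma_curve.kind != "nma_fluorescence":
        raise ValueError("IU conversion requires an Nma fluorescence curve")
    if supernatant_ul <= 0:
        raise ValueError("supernatant volume must be positive")
    nmol_per_min = dF_per_min / nma_curve.slope
    umol_per_min = nmol_per_min / 1e3
    return umol_per_min / (supernatant_ul / 1e3)


def specificity_profile(activities_iu_per_ml, amino_acids=AMINO_ACIDS_19):
    """Normalize a 19-residue activity panel to its maximum (= 100%)."""
    a = np.asarray(list(activities_iu_per_ml), dtype=float)
    aa = tuple(amino_acids)
    if len(a) != 19 or len(aa) != 19:
        raise ValueError(f"specificity panel must have 19 residues, got {len(a)}")
    if np.any(a < 0):
        raise ValueError("activities must be non-negative")
    peak = a.max()
    if peak <= 0:
        raise ValueError("all panel activities are zero")
    return SpecificityProfile(
        amino_acids=aa,
        activities_iu_per_ml=a,
        relative_pct=100.0 * a / peak,
    )
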