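"""Synthetic cohorts and the packaged participant table.

The only measured data this package ships is the 16-participant table of
resting motor thresholds (RMT, %MSO) and coil-to-cortex distances for the
two stimulation targets (M1 and DLPFC).  Everything else — head geometry,
cortical folding, coil drive — is generated synthetically so that the full
dosing pipeline can run without any external downloads.

Synthetic participants carry a spherical head (scalp + cortex radii) and
two region patches whose folding parameters differ:  the "M1-like" region
folds deeply with a short gyral wavelength, the "DLPFC-like" region is
shallower and broader.  Scalp and cortex radii are shared between the two
regions of a participant, so scalp-to-cortex distance is matched by
construction — mirroring the non-significant depth difference in the
measured table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Table1Record",
    "RegionSpec",
    "HeadParams",
    "Participant",
    "load_table1_fixture",
    "table1_path",
    "sample_cohort",
    "cohort_to_csv",
    "default_head_params",
    "M1",
    "DLPFC",
]

#: canonical region keys used throughout the package
M1 = "M1"
DLPFC = "DLPFC"

# Geodesic arc length (mm) of the clinical "5-cm rule" separating the two
# patch centers on the scalp.
FIVE_CM_RULE_MM = 50.0


@dataclass(frozen=True)
class Table1Record:
    """One row of the packaged participant table."""

    id: str
    rmt_pct_mso: int
    depth_m1_mm: float
    depth_dlpfc_mm: float


@dataclass(frozen=True)
class RegionSpec:
    """Folding parameters of one cortical region patch.

    The synthetic cortex is a sphere of radius ``cortex_radius_mm`` whose
    patch is corrugated radially inward by

        s(u) = sulcal_depth * ((1 - cos(2*pi*u / wavelength)) / 2) ** crown_exponent

    along a corrugation coordinate ``u`` in the patch tangent plane.  The
    crown exponent shapes the fold cross-section: values above 1 give
    broad, flat gyral crowns with narrow deep sulci (a hand-knob-like
    prominent gyrus), values below 1 give rounded crowns with broad
    valleys so that more cortex sits at depth.  This shape term — not the
    matched scalp-to-cortex distance — is what differentiates the regions'
    exposure to the induced field.
    """

    gyral_wavelength_mm: float
    sulcal_depth_mm: float
    patch_center_direction: tuple[float, float, float]
    patch_angular_radius_deg: float = 22.0
    crown_exponent: float = 1.0

    def __post_init__(self):
        if self.gyral_wavelength_mm <= 0:
            raise ValueError("gyral wavelength must be > 0")
        if self.sulcal_depth_mm < 0:
            raise ValueError("sulcal depth must be >= 0")
        if self.crown_exponent <= 0:
            raise ValueError("crown exponent must be > 0")


@dataclass(frozen=True)
class HeadParams:
    """Spherical head geometry plus per-region folding."""

    scalp_radius_mm: float
    cortex_radius_mm: float
    regions: dict[str, RegionSpec]

    def __post_init__(self):
        if not self.cortex_radius_mm < self.scalp_radius_mm:
            raise ValueError("cortex radius must be smaller than scalp radius")


@dataclass(frozen=True)
class Participant:
    id: str
    rmt_pct_mso: int
    head_params: HeadParams
    seed: int

    def __post_init__(self):
        if not 1 <= self.rmt_pct_mso <= 100:
            raise ValueError("RMT must be in [1, 100] %MSO")


def _dlpfc_center_direction(scalp_radius_mm: float) -> tuple[float, float, float]:
    # The DLPFC-like patch center sits where the 5-cm scalp geodesic from
    # the M1-like patch center (+z) lands, moving anterior (+x).
    beta = FIVE_CM_RULE_MM / scalp_radius_mm
    return (float(np.sin(beta)), 0.0, float(np.cos(beta)))


def default_head_params() -> HeadParams:
    """Reference head: scalp 85 mm, cortex 78 mm.

    The M1-like region folds deeply with a short wavelength (12 mm / 12 mm)
    and a broad-crown profile (crown_exponent 2), like the prominent
    precentral hand knob; the DLPFC-like region is shallower and broader
    (8 mm / 16 mm) with rounded folds (crown_exponent 0.7) that keep a
    larger share of cortex at depth.  Identical drive therefore produces a
    stronger ROI-mean field in the M1-like region while scalp-to-cortex
    distance stays matched by construction.
    """
    scalp = 85.0
    return HeadParams(
        scalp_radius_mm=scalp,
        cortex_radius_mm=78.0,
        regions={
            M1: RegionSpec(
                gyral_wavelength_mm=12.0,
                sulcal_depth_mm=12.0,
                patch_center_direction=(0.0, 0.0, 1.0),
                crown_exponent=2.0,
            ),
            DLPFC: RegionSpec(
                gyral_wavelength_mm=16.0,
                sulcal_depth_mm=8.0,
                patch_center_direction=_dlpfc_center_direction(scalp),
                crown_exponent=0.7,
            ),
        },
    )


def table1_path() -> Path:
    """Filesystem path of the packaged participant table."""
    return Path(resources.files("tmsdose").joinpath("data/table1.tsv"))


def load_table1_fixture(path: str | Path | None = None) -> list[Table1Record]:
    """Load the packaged 16-participant table (RMT and cortical depths).

    Raises ``ValueError`` naming the file if the table is corrupted.
    """
    p = Path(path) if path is not None else table1_path()
    records: list[Table1Record] = []
    try:
        with open(p, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames != ["id", "rmt", "depth_m1", "depth_dlpfc"]:
                raise ValueError(f"unexpected header {reader.fieldnames!r}")
            for row in reader:
                rec = Table1Record(
                    id=row["id"],
                    rmt_pct_mso=int(row["rmt"]),
                    depth_m1_mm=float(row["depth_m1"]),
                    depth_dlpfc_mm=float(row["depth_dlpfc"]),
                )
                if rec.depth_m1_mm <= 0 or rec.depth_dlpfc_mm <= 0:
                    raise ValueError(f"non-positive depth in row {row!r}")
                records.append(rec)
    except (OSError, ValueError, KeyError) as exc:
        raise ValueError(f"corrupted participant table at {p}: {exc}") from exc
    if len(records) != 16:
        raise ValueError(f"corrupted participant table at {p}: expected 16 records, got {len(records)}")
    if len({r.id for r in records}) != len(records):
        raise ValueError(f"corrupted participant table at {p}: duplicate ids")
    return records


# RMT range observed in the packaged table; the synthetic cohort draws
# uniformly over it (16 points are too few to justify a parametric fit).
RMT_RANGE = (41, 75)

# Coefficients of variation for the jitter applied around the default head
# parameters.  Radii vary little across adult heads (~2%); folding geometry
# varies more (~10%).
CV_RADII = 0.02
CV_FOLDING = 0.10


def sample_cohort(
    n: int,
    seed: int,
    params: HeadParams | None = None,
    cv_radii: float = CV_RADII,
    cv_folding: float = CV_FOLDING,
) -> list[Participant]:
    """Draw ``n`` synthetic participants, deterministically from ``seed``.

    RMTs are uniform integers over the observed range; head parameters are
    log-normally jittered around the defaults with the documented
    coefficients of variation.  Scalp and cortex radii are shared between
    the two regions of each participant.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base = params if params is not None else default_head_params()
    rng = np.random.default_rng(seed)
    cohort: list[Participant] = []
    for i in range(n):
        rmt = int(rng.integers(RMT_RANGE[0], RMT_RANGE[1] + 1))
        scalp = base.scalp_radius_mm * _lognorm(rng, cv_radii)
        # keep the scalp-cortex shell thickness proportionally jittered too
        cortex = scalp - (base.scalp_radius_mm - base.cortex_radius_mm) * _lognorm(rng, cv_radii)
        regions = {}
        for name, spec in base.regions.items():
            regions[name] = replace(
                spec,
                gyral_wavelength_mm=spec.gyral_wavelength_mm * _lognorm(rng, cv_folding),
                sulcal_depth_mm=spec.sulcal_depth_mm * _lognorm(rng, cv_folding),
            )
        head = HeadParams(scalp_radius_mm=scalp, cortex_radius_mm=cortex, regions=regions)
        cohort.append(
            Participant(
                id=f"S{i + 1:02d}",
                rmt_pct_mso=rmt,
                head_params=head,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return cohort


def _lognorm(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplier with coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma2 = np.log(1.0 + cv**2)
    return float(np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2))))


def cohort_to_csv(cohort: list[Participant], path: str | Path) -> None:
    """Export a cohort, one row per participant."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id", "rmt_pct_mso", "scalp_radius_mm", "cortex_radius_mm",
             "region", "gyral_wavelength_mm", "sulcal_depth_mm", "seed"]
        )
        for p in cohort:
            for name, spec in p.head_params.regions.items():
                w.writerow(
                    [p.id, p.rmt_pct_mso,
                     f"{p.head_params.scalp_radius_mm:.6f}",
                     f"{p.head_params.cortex_radius_mm:.6f}",
                     name,
                     f"{spec.gyral_wavelength_mm:.6f}",
                     f"{spec.sulcal_depth_mm:.6f}",
                     p.seed]
                )
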