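"""Accurate-mass metabolite annotation against compound databases.

Features are matched to compounds (HMDB/LIPID MAPS-style tables of id,
name, formula, monoisotopic mass) through an adduct model: each adduct
hypothesis inverts the observed m/z to a neutral monoisotopic mass
``M = (mz * |z| - mass_shift) / multimer`` and every compound within the
ppm tolerance window yields a hit. One feature may be annotated under
several adducts; all hits are reported, ranked by absolute ppm error.

Formula masses come from monoisotopic (most-abundant-isotope) atomic
masses; the proton mass used for charge carriers is 1.00727646 Da and
electron masses are included in the adduct shifts.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Sequence

import numpy as np
from pyteomics import mass as _pyteomics_mass
from pyteomics.auxiliary import PyteomicsError

from .errors import ConfigurationError, FormatError, FormulaError, ParameterError
from .model import FeatureRecord

PROTON_MASS = 1.00727646  # Da, H+ (H atom minus one electron)
ELECTRON_MASS = 0.00054858  # Da


def formula_monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of an elemental formula, e.g. ``"C6H12O6"``.

    Uses most-abundant-isotope masses (C = 12 exactly).
    """
    try:
        return float(_pyteomics_mass.calculate_mass(formula=formula))
    except PyteomicsError as exc:
        raise FormulaError(f"cannot parse formula {formula!r}: {exc}") from None


@dataclass(frozen=True)
class CompoundRecord:
    """One database entry; mass may be given or derived from the formula."""

    compound_id: str
    name: str
    formula: str | None
    monoisotopic_mass: float
    source: Literal["hmdb", "lipidmaps", "custom"] = "custom"

    def __post_init__(self) -> None:
        if not self.monoisotopic_mass > 0:
            raise ParameterError(
                f"compound {self.compound_id!r}: monoisotopic_mass must be > 0"
            )
        if self.formula:
            m = formula_monoisotopic_mass(self.formula)
            if abs(m - self.monoisotopic_mass) > 0.001:
                raise ParameterError(
                    f"compound {self.compound_id!r}: stored mass "
                    f"{self.monoisotopic_mass} disagrees with formula mass {m:.6f}"
                )


@dataclass(frozen=True)
class AdductSpec:
    """Ionization adduct: observed m/z = (multimer * M + mass_shift) / |charge|.

    ``mass_shift`` is the signed total mass added or removed, electrons
    included (e.g. +1.00727646 for [M+H]+).
    """

    name: str
    charge: int
    multimer: int = 1
    mass_shift: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.charge) < 1:
            raise ParameterError(f"adduct {self.name!r}: |charge| must be >= 1")
        if self.multimer < 1:
            raise ParameterError(f"adduct {self.name!r}: multimer must be >= 1")

    def neutral_mass(self, mz: float) -> float:
        """Invert an observed m/z to the neutral monoisotopic mass."""
        return (mz * abs(self.charge) - self.mass_shift) / self.multimer

    def mz_for(self, neutral_mass: float) -> float:
        """Theoretical m/z of a neutral mass under this adduct."""
        return (self.multimer * neutral_mass + self.mass_shift) / abs(self.charge)


def feature_neutral_mass(mz: float, adduct: AdductSpec) -> float:
    """Neutral monoisotopic mass implied by an m/z under an adduct model."""
    if not mz > 0:
        raise ParameterError(f"mz must be > 0, got {mz}")
    return adduct.neutral_mass(mz)


_NA = 22.98976928 - ELECTRON_MASS
_K = 38.96370649 - ELECTRON_MASS
_NH4 = 14.0030740048 + 4 * 1.00782503207 - ELECTRON_MASS
_CL = 34.96885268 + ELECTRON_MASS
_FORMATE = 12.0 + 1.00782503207 + 2 * 15.99491461956 + ELECTRON_MASS

POSITIVE_ADDUCTS: tuple[AdductSpec, ...] = (
    AdductSpec("[M+H]+", charge=1, multimer=1, mass_shift=PROTON_MASS),
    AdductSpec("[M+Na]+", charge=1, multimer=1, mass_shift=_NA),
    AdductSpec("[M+K]+", charge=1, multimer=1, mass_shift=_K),
    AdductSpec("[M+NH4]+", charge=1, multimer=1, mass_shift=_NH4),
    AdductSpec("[2M+H]+", charge=1, multimer=2, mass_shift=PROTON_MASS),
)
NEGATIVE_ADDUCTS: tuple[AdductSpec, ...] = (
    AdductSpec("[M-H]-", charge=-1, multimer=1, mass_shift=-PROTON_MASS),
    AdductSpec("[M+Cl]-", charge=-1, multimer=1, mass_shift=_CL),
    AdductSpec("[M+HCOO]-", charge=-1, multimer=1, mass_shift=_FORMATE),
    AdductSpec("[2M-H]-", charge=-1, multimer=2, mass_shift=-PROTON_MASS),
)
ADDUCT_SETS = {"positive": POSITIVE_ADDUCTS, "negative": NEGATIVE_ADDUCTS}


@dataclass(frozen=True)
class AnnotationHit:
    feature_id: str
    compound_id: str
    compound_name: str
    adduct_name: str
    observed_neutral_mass: float
    ppm_error: float  # signed, (observed - theoretical) / theoretical * 1e6


def search_accurate_mass(
    features: Sequence[FeatureRecord],
    db: Sequence[CompoundRecord],
    adducts: Sequence[AdductSpec] = POSITIVE_ADDUCTS,
    ppm_tol: float = 5.0,
) -> list[AnnotationHit]:
    """Accurate-mass search of every feature x adduct against the database.

    A compound with monoisotopic mass ``m`` is a hit for an observed neutral
    mass ``M`` when ``|M - m| / m * 1e6 <= ppm_tol``. The candidate window
    is located by binary search on the mass-sorted database. Hits are
    grouped per feature (input order) and sorted by \\|ppm error\\|
    ascending, ties broken by compound id.
    """
    if not db:
        raise ConfigurationError("compound database is empty")
    if not ppm_tol > 0:
        raise ParameterError("ppm_tol must be > 0")
    sorted_db = sorted(db, key=lambda c: (c.monoisotopic_mass, c.compound_id))
    masses = np.array([c.monoisotopic_mass for c in sorted_db])
    tol = ppm_tol * 1e-6
    hits: list[AnnotationHit] = []
    for feat in features:
        feat_hits: list[AnnotationHit] = []
        for adduct in adducts:
            observed = adduct.neutral_mass(feat.mz)
            if observed <= 0:
                continue
            # |observed - m| <= tol * m  <=>  m in [observed/(1+tol), observed/(1-tol)]
            lo = np.searchsorted(masses, observed / (1.0 + tol), side="left")
            hi = np.searchsorted(masses, observed / (1.0 - tol), side="right")
            for c in sorted_db[lo:hi]:
                ppm = (observed - c.monoisotopic_mass) / c.monoisotopic_mass * 1e6
                if abs(ppm) <= ppm_tol:
                    feat_hits.append(
                        AnnotationHit(
                            feature_id=feat.feature_id,
                            compound_id=c.compound_id,
                            compound_name=c.name,
                            adduct_name=adduct.name,
                            observed_neutral_mass=observed,
                            ppm_error=ppm,
                        )
                    )
        feat_hits.sort(key=lambda h: (abs(h.ppm_error), h.compound_id))
        hits.extend(feat_hits)
    return hits


# ---------------------------------------------------------------------------
# Table I/O

def read_compound_table(path: str | os.PathLike) -> list[CompoundRecord]:
    """Read a compound database TSV with columns compound_id, name, formula,
    monoisotopic_mass, source. Mass may be blank when a formula is given."""
    records: list[CompoundRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"compound_id", "name"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(
                "compound table needs at least columns compound_id and name"
            )
        for row in reader:
            formula = (row.get("formula") or "").strip() or None
            mass_cell = (row.get("monoisotopic_mass") or "").strip()
            if mass_cell:
                mass = float(mass_cell)
            elif formula:
                mass = formula_monoisotopic_mass(formula)
            else:
                raise FormatError(
                    f"compound {row['compound_id']!r} has neither formula nor mass"
                )
            records.append(
                CompoundRecord(
                    compound_id=row["compound_id"],
                    name=row["name"],
                    formula=formula,
                    monoisotopic_mass=mass,
                    source=(row.get("source") or "custom").strip().lower(),  # type: ignore[arg-type]
                )
            )
    if not records:
        raise FormatError("compound table is empty")
    return records


def read_adduct_table(path: str | os.PathLike) -> list[AdductSpec]:
    """Read an adduct TSV with columns name, charge, multimer, mass_shift."""
    adducts: list[AdductSpec] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            adducts.append(
                AdductSpec(
                    name=row["name"],
                    charge=int(row["charge"]),
                    multimer=int(row.get("multimer") or 1),
                    mass_shift=float(row["mass_shift"]),
                )
            )
    if not adducts:
        raise FormatError("adduct table is empty")
    return adducts


def load_bundled_compounds() -> list[CompoundRecord]:
    """The curated compound fixture shipped with the package (~50 common
    metabolites and lipids with CHNOPS formulas)."""
    ref = resources.files("metaproc").joinpath("data/compounds_curated.tsv")
    with resources.as_file(ref) as path:
        return read_compound_table(path)


def write_annotation_table(
    hits: Sequence[AnnotationHit],
    features: Sequence[FeatureRecord],
    path: str | os.PathLike,
) -> None:
    """TSV of hits joined to feature m/z and RT; unannotated features get a
    single row with empty compound fields."""
    by_id = {f.feature_id: f for f in features}
    annotated = {h.feature_id for h in hits}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["feature_id", "mz", "rt", "compound_id", "compound_name",
             "adduct", "neutral_mass", "ppm_error"]
        )
        for h in hits:
            f = by_id[h.feature_id]
            writer.writerow(
                [h.feature_id, repr(f.mz), repr(f.rt), h.compound_id,
                 h.compound_name, h.adduct_name,
                 f"{h.observed_neutral_mass:.6f}", f"{h.ppm_error:.3f}"]
            )
        for f in features:
            if f.feature_id not in annotated:
                writer.writerow([f.feature_id, repr(f.mz), repr(f.rt), "", "", "", "", ""])
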