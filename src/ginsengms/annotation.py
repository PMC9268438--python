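"""Ginsenoside annotation of aligned LC-MS features.

Features are matched to a packaged reference database of 69
characteristic ginsenosides (negative ion mode) by

* computing the monoisotopic mass of each compound's molecular
  formula,
* deriving the theoretical m/z of its adduct ion — ginsenosides
  ionize mainly as the deprotonated molecule [M-H]- or the formate
  adduct [M+HCOO]- — and
* accepting matches within a ppm mass window and a retention-time
  window (isomeric ginsenosides share a formula and are told apart
  by RT).

Diagnostic aglycone fragments classify a compound into the three
ginsenoside families: protopanaxatriol (PPT, fragment near m/z
475.38), protopanaxadiol (PPD, near 459.38) and oleanolic acid (OA,
near 455.35); sugar chains strip off under collision-induced
dissociation while the triterpene core survives.

Adduct m/z arithmetic includes the electron mass by default
(an anion carries one extra electron); a ``convention`` switch
provides neutral-fragment arithmetic because published tables do not
always follow a single convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from ginsengms.features import FeatureTable

__all__ = [
    "ELEMENT_MASSES",
    "ELECTRON_MASS",
    "GinsenosideRecord",
    "AnnotationHit",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "theoretical_mz",
    "classify_aglycone",
    "annotate_features",
    "load_reference_db",
]

# Monoisotopic atomic masses (Da). Carbon defines the scale.
ELEMENT_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "O": 15.9949146221,
    "N": 14.0030740052,
}
ELECTRON_MASS = 0.0005485799

ION_TYPES = ("[M-H]-", "[M+HCOO]-")

# Diagnostic aglycone fragment m/z (accurate values recur in published
# fragment lists; nominal 475/459/455).
AGLYCONE_FRAGMENTS = {"PPT": 475.38, "PPD": 459.38, "OA": 455.35}

AdductConvention = Literal["electron", "neutral"]


@dataclass(frozen=True)
class GinsenosideRecord:
    """One reference compound: formula, adduct ion, RT and fragments."""

    index: int
    rt: float
    name: str
    formula: str
    mass_ion_mz: float
    ion_type: str
    error_ppm: float
    fragment_ions: tuple[float, ...]
    aglycone_class: str = "unknown"
    reference: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if self.ion_type not in ION_TYPES:
            raise ValueError(f"unknown ion type {self.ion_type!r}")
        parse_formula(self.formula)  # raises on malformed formulas


@dataclass(frozen=True)
class AnnotationHit:
    """A feature matched to a reference record."""

    feature_index: int
    record: GinsenosideRecord
    observed_mz: float
    theoretical_mz: float
    ppm_error: float
    rt_delta: float


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(s: str) -> dict[str, int]:
    """Parse an elemental formula like ``"C42H72O14"`` into element counts.

    Raises ``ValueError`` (with the offending position) for malformed
    strings or elements outside the internal mass table.
    """
    if not s:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"malformed formula {s!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ELEMENT_MASSES:
            raise ValueError(
                f"unsupported element {el!r} in formula {s!r} at position {pos}"
            )
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return counts


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Monoisotopic mass (Da) of an element-count map."""
    total = 0.0
    for el, n in counts.items():
        if el not in ELEMENT_MASSES:
            raise ValueError(f"no monoisotopic mass for element {el!r}")
        total += ELEMENT_MASSES[el] * n
    return total


def _proton_mass(convention: AdductConvention) -> float:
    # "electron": the ion keeps its extra electron ([M-H]- loses H+).
    # "neutral": plain hydrogen-atom arithmetic, no electron bookkeeping.
    if convention == "electron":
        return ELEMENT_MASSES["H"] - ELECTRON_MASS
    return ELEMENT_MASSES["H"]


def _formate_mass(convention: AdductConvention) -> float:
    hcoo = ELEMENT_MASSES["C"] + ELEMENT_MASSES["H"] + 2 * ELEMENT_MASSES["O"]
    if convention == "electron":
        return hcoo + ELECTRON_MASS
    return hcoo


def adduct_mz(
    M: float, ion_type: str, convention: AdductConvention = "electron"
) -> float:
    """Theoretical m/z of the [M-H]- or [M+HCOO]- ion of neutral mass ``M``."""
    if M <= 0:
        raise ValueError(f"neutral mass must be positive, got {M}")
    if ion_type == "[M-H]-":
        return M - _proton_mass(convention)
    if ion_type == "[M+HCOO]-":
        return M + _formate_mass(convention)
    raise ValueError(f"unknown ion type {ion_type!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def theoretical_mz(
    record: GinsenosideRecord, convention: AdductConvention = "electron"
) -> float:
    """Theoretical adduct m/z of a reference record's formula."""
    return adduct_mz(
        monoisotopic_mass(parse_formula(record.formula)), record.ion_type, convention
    )


def classify_aglycone(
    fragments: Iterable[float], tol: float = 0.05
) -> str:
    """Classify a fragment list into PPT / PPD / OA / unknown.

    A fragment within ``tol`` Da of 475.38 marks protopanaxatriol,
    459.38 protopanaxadiol, 455.35 oleanolic acid; when several match,
    precedence is PPT > PPD > OA.
    """
    frags = np.asarray(list(fragments), dtype=float)
    if frags.size == 0:
        return "unknown"
    for cls in ("PPT", "PPD", "OA"):
        if np.any(np.abs(frags - AGLYCONE_FRAGMENTS[cls]) <= tol):
            return cls
    return "unknown"


def load_reference_db() -> list[GinsenosideRecord]:
    """Load the packaged 69-compound ginsenoside reference database.

    The table lists, per compound: retention time, name (isomers keep
    the "or its isomer" qualifier), molecular formula, measured adduct
    m/z, ion type, published ppm error and MS/MS fragment ions.  The
    ``notes`` column flags entries corrected for evident typographical
    inconsistencies (formula/ion-type against the printed m/z).
    """
    with resources.files("ginsengms.data").joinpath(
        "ginsenosides_table1.csv"
    ).open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    records = []
    for r in df.itertuples():
        frags = tuple(
            float(x) for x in str(r.fragment_ions).split(";") if x.strip()
        )
        records.append(
            GinsenosideRecord(
                index=int(r.no),
                rt=float(r.rt_min),
                name=str(r.name),
                formula=str(r.formula),
                mass_ion_mz=float(r.mass_ion_mz),
                ion_type=str(r.ion_type),
                error_ppm=float(r.error_ppm),
                fragment_ions=frags,
                aglycone_class=classify_aglycone(frags),
                reference=str(r.reference),
                notes=str(r.notes),
            )
        )
    return records


def annotate_features(
    ft: FeatureTable,
    db: Sequence[GinsenosideRecord],
    mz_tol_ppm: float = 15.0,
    rt_tol: float = 0.5,
    convention: AdductConvention = "electron",
) -> list[AnnotationHit]:
    """Match aligned features against the reference database.

    A feature hits every record whose theoretical adduct m/z is within
    ``mz_tol_ppm`` and whose RT is within ``rt_tol`` minutes; a feature
    may therefore collect zero hits or several (isomers share a
    formula).  Hits are sorted by absolute ppm error, ties by feature
    then record index.
    """
    if len(db) == 0:
        raise ValueError("annotation database is empty")
    if mz_tol_ppm <= 0 or rt_tol <= 0:
        raise ValueError("annotation tolerances must be positive")
    theos = np.array([theoretical_mz(rec, convention) for rec in db])
    rts = np.array([rec.rt for rec in db])
    hits: list[AnnotationHit] = []
    for j in range(ft.n_features):
        mz = ft.feature_mz[j]
        rt = ft.feature_rt[j]
        ppm = (mz - theos) / theos * 1e6
        ok = (np.abs(ppm) <= mz_tol_ppm) & (np.abs(rt - rts) <= rt_tol)
        for ri in np.nonzero(ok)[0]:
            hits.append(
                AnnotationHit(
                    feature_index=j,
                    record=db[ri],
                    observed_mz=float(mz),
                    theoretical_mz=float(theos[ri]),
                    ppm_error=float(ppm[ri]),
                    rt_delta=float(rt - rts[ri]),
                )
            )
    hits.sort(key=lambda h: (abs(h.ppm_error), h.feature_index, h.record.index))
    return hits


def hits_to_frame(hits: Sequence[AnnotationHit]) -> pd.DataFrame:
    """Tabulate annotation hits for export."""
    return pd.DataFrame(
        {
            "feature_index": [h.feature_index for h in hits],
            "compound": [h.record.name for h in hits],
            "formula": [h.record.formula for h in hits],
            "ion_type": [h.record.ion_type for h in hits],
            "aglycone_class": [h.record.aglycone_class for h in hits],
            "observed_mz": [h.observed_mz for h in hits],
            "theoretical_mz": [h.theoretical_mz for h in hits],
            "ppm_error": [h.ppm_error for h in hits],
            "rt_delta": [h.rt_delta for h in hits],
        }
    )
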