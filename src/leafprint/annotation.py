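"""Accurate-mass annotation and consensus structural classification.

Fingerprint-level features carry no chromatographic or MS/MS evidence, so
annotation is by accurate mass alone: a feature's observed m/z is matched
against the theoretical m/z of every (compound, adduct) combination in a
local compound reference, ``(n*M + shift)/z`` for an adduct taking ``n``
copies of the neutral molecule ``M``.  Matches within a ppm tolerance
(default 3 ppm) become candidates; compounds from the primary source
(e.g. a KEGG-style table) are searched first and a fallback source
(PubChem-style) is consulted only when the primary yields nothing.

Because a single accurate mass rarely pins down one compound, each feature
receives a *consensus* structural classification: walking a chemical
taxonomy (kingdom -> superclass -> class -> ...) from the top, a level is
accepted while at least a threshold fraction (default 66%) of the still-
consistent candidate compounds agree on one term, and the walk stops at the
first failure.

Monoisotopic masses are computed from the compiled-in atomic mass table
(CODATA/AME values); charged-species m/z accounts for the electron mass.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("leafprint")

# ---------------------------------------------------------------------------
# atomic masses and formulas
# ---------------------------------------------------------------------------

#: monoisotopic atomic masses, Da (most abundant isotope)
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Mg": 23.985041697,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Se": 79.9165213,
    "Br": 78.9183371,
    "I": 126.904473,
}

ELECTRON_MASS = 0.000548579909

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in ATOMIC_MASSES:
            raise ValueError(f"unknown element {elem!r} in formula {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic mass of a neutral molecular formula, Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ATOMIC_MASSES[el] * n for el, n in counts.items())


# ---------------------------------------------------------------------------
# adduct rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdductRule:
    """Electrospray adduct: observed m/z = (n*M + shift)/z.

    ``shift`` already includes the electron mass of the charge carrier.
    ``requires`` gives minimum element counts the neutral formula must have
    for the adduct to be formable (e.g. deprotonation needs a proton).
    """

    name: str
    polarity: str           # "positive" | "negative"
    n: int                  # multimer count
    shift: float            # Da
    z: int = 1
    requires: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n < 1 or self.z < 1:
            raise ValueError("adduct multimer count and charge must be >= 1")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")

    def applicable(self, formula: str | dict[str, int]) -> bool:
        if not self.requires:
            return True
        counts = parse_formula(formula) if isinstance(formula, str) else formula
        return all(counts.get(el, 0) >= k for el, k in self.requires)


_H = ATOMIC_MASSES["H"]
_PROTON = _H - ELECTRON_MASS

DEFAULT_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("[M+H]+", "positive", 1, _PROTON),
    AdductRule("[M+Na]+", "positive", 1, ATOMIC_MASSES["Na"] - ELECTRON_MASS),
    AdductRule("[M+K]+", "positive", 1, ATOMIC_MASSES["K"] - ELECTRON_MASS),
    AdductRule("[M+NH4]+", "positive", 1,
               ATOMIC_MASSES["N"] + 4 * _H - ELECTRON_MASS),
    AdductRule("[2M+H]+", "positive", 2, _PROTON),
    AdductRule("[M-H]-", "negative", 1, -_H + ELECTRON_MASS, requires=(("H", 1),)),
    AdductRule("[M+Cl]-", "negative", 1, ATOMIC_MASSES["Cl"] + ELECTRON_MASS),
    AdductRule("[M+HCOO]-", "negative", 1,
               _H + ATOMIC_MASSES["C"] + 2 * ATOMIC_MASSES["O"] + ELECTRON_MASS),
    AdductRule("[2M-H]-", "negative", 2, -_H + ELECTRON_MASS, requires=(("H", 1),)),
)


def theoretical_mz(mass: float, rule: AdductRule,
                   formula: str | dict[str, int] | None = None) -> float:
    """m/z of the ion ``rule`` forms from a neutral of monoisotopic ``mass``."""
    if formula is not None and not rule.applicable(formula):
        raise ValueError(f"adduct {rule.name} not formable by {formula}")
    return (rule.n * mass + rule.shift) / rule.z


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million, relative to theoretical."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


# ---------------------------------------------------------------------------
# compound reference
# ---------------------------------------------------------------------------

@dataclass
class FormulaDB:
    """Compound reference: formulas, masses, taxonomy lineages, pathways.

    ``table`` columns: compound_id, formula, mass, source ("primary" |
    "fallback"), lineage (list of taxonomy terms, most general first),
    pathway_ids (list).
    """

    table: pd.DataFrame

    REQUIRED = ("compound_id", "formula", "mass", "source", "lineage", "pathway_ids")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"FormulaDB missing columns {missing}")
        bad_src = set(self.table["source"]) - {"primary", "fallback"}
        if bad_src:
            raise ValueError(f"unknown sources {bad_src}")
        for _, row in self.table.iterrows():
            if row["mass"] <= 0:
                raise ValueError(f"{row['compound_id']}: non-positive mass")
            expect = formula_mass(row["formula"])
            if abs(expect - row["mass"]) > 1e-4:
                raise ValueError(
                    f"{row['compound_id']}: mass {row['mass']} inconsistent with "
                    f"formula {row['formula']} (expected {expect:.5f})")
            if not row["lineage"]:
                raise ValueError(f"{row['compound_id']}: empty taxonomy lineage")
        if self.table["compound_id"].duplicated().any():
            raise ValueError("duplicate compound ids")

    def __len__(self) -> int:
        return len(self.table)

    # -- persistence: lineage and pathway lists are ';'-joined in CSV -------
    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out["lineage"] = out["lineage"].map(";".join)
        out["pathway_ids"] = out["pathway_ids"].map(";".join)
        out.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def read(cls, path: str | Path) -> "FormulaDB":
        raw = pd.read_csv(path)
        raw["lineage"] = raw["lineage"].fillna("").map(
            lambda s: [t for t in str(s).split(";") if t])
        raw["pathway_ids"] = raw["pathway_ids"].fillna("").map(
            lambda s: [t for t in str(s).split(";") if t])
        return cls(raw)


# ---------------------------------------------------------------------------
# formula assignment
# ---------------------------------------------------------------------------

@dataclass
class AnnotationRecord:
    """Annotation of one m/z bin: candidates plus consensus classification."""

    bin_id: str
    mz: float
    mode: str
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)
    consensus_lineage: list[str] = field(default_factory=list)
    consensus_depth: int = 0
    level_fractions: list[float] = field(default_factory=list)

    @property
    def classified(self) -> bool:
        return self.consensus_depth > 0

    @property
    def matched_compounds(self) -> list[str]:
        if self.candidates.empty:
            return []
        seen: list[str] = []
        for ids in self.candidates["compound_ids"]:
            for cid in ids:
                if cid not in seen:
                    seen.append(cid)
        return seen


_CAND_COLUMNS = ("formula", "adduct", "theoretical_mz", "ppm_error",
                 "compound_ids", "source")


def assign_formulas(bin_id: str, mz: float, mode: str, db: FormulaDB,
                    rules: tuple[AdductRule, ...] = DEFAULT_ADDUCTS,
                    tolerance_ppm: float = 3.0) -> AnnotationRecord:
    """Collect every (formula, adduct) candidate within ``tolerance_ppm``.

    Primary-source compounds are searched first; the fallback source is
    consulted only when the primary search yields no candidate.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    if len(db) == 0:
        raise ValueError("empty FormulaDB")
    mode_rules = [r for r in rules if r.polarity == mode]
    if not mode_rules:
        raise ValueError(f"no adduct rules for mode {mode!r}")

    def search(source: str) -> pd.DataFrame:
        sub = db.table[db.table["source"] == source]
        rows = []
        # candidates are keyed by (formula, adduct); all compounds sharing the
        # formula are attached to the same candidate
        for formula, grp in sub.groupby("formula", sort=True):
            counts = parse_formula(formula)
            mass = formula_mass(counts)
            for rule in mode_rules:
                if not rule.applicable(counts):
                    continue
                tm = theoretical_mz(mass, rule)
                err = ppm_error(mz, tm)
                if abs(err) <= tolerance_ppm:
                    rows.append((formula, rule.name, tm, err,
                                 list(grp["compound_id"]), source))
        return pd.DataFrame(rows, columns=_CAND_COLUMNS)

    cands = search("primary")
    if cands.empty:
        cands = search("fallback")
    return AnnotationRecord(bin_id=bin_id, mz=mz, mode=mode, candidates=cands)


# ---------------------------------------------------------------------------
# consensus classification
# ---------------------------------------------------------------------------

def consensus_classification(lineages: list[list[str]],
                             threshold: float = 0.66
                             ) -> tuple[list[str], int, list[float]]:
    """Deepest taxonomy lineage shared by >= ``threshold`` of the candidates.

    Walks levels from the most general term.  At each level the modal term is
    computed among the compounds still consistent with the accepted prefix;
    the level is accepted iff the modal frequency (over all consistent
    compounds, including those whose lineage ends above this level) reaches
    the threshold.  An exact tie between two modal terms at the threshold
    stops the walk at the previous level.
    """
    if not lineages:
        return [], 0, []
    accepted: list[str] = []
    fractions: list[float] = []
    consistent = list(lineages)
    level = 0
    while True:
        terms = [lin[level] for lin in consistent if len(lin) > level]
        if not terms:
            break
        counts = Counter(terms)
        top_term, top_n = counts.most_common(1)[0]
        frac = top_n / len(consistent)
        if frac < threshold:
            break
        # tie at the modal count: ambiguous, stop conservatively
        if sum(1 for t, c in counts.items() if c == top_n) > 1:
            break
        accepted.append(top_term)
        fractions.append(frac)
        consistent = [lin for lin in consistent
                      if len(lin) > level and lin[level] == top_term]
        level += 1
    return accepted, len(accepted), fractions


def annotate_record(record: AnnotationRecord, db: FormulaDB,
                    threshold: float = 0.66) -> AnnotationRecord:
    """Fill a record's consensus classification from its matched compounds."""
    compounds = record.matched_compounds
    if not compounds:
        record.consensus_lineage, record.consensus_depth, record.level_fractions = [], 0, []
        return record
    lut = db.table.set_index("compound_id")["lineage"]
    lineages = [list(lut[cid]) for cid in compounds]
    lineage, depth, fracs = consensus_classification(lineages, threshold)
    record.consensus_lineage = lineage
    record.consensus_depth = depth
    record.level_fractions = fracs
    return record


def annotate_matrix(matrix, db: FormulaDB,
                    rules: tuple[AdductRule, ...] = DEFAULT_ADDUCTS,
                    tolerance_ppm: float = 3.0,
                    consensus_threshold: float = 0.66) -> list[AnnotationRecord]:
    """Annotate every bin of a FeatureMatrix (uses the bins' accurate m/z)."""
    records = []
    for bid in matrix.bin_ids:
        mode = matrix.bin_info.loc[bid, "mode"]
        mz = float(matrix.bin_info.loc[bid, "mz"])
        rec = assign_formulas(bid, mz, mode, db, rules, tolerance_ppm)
        records.append(annotate_record(rec, db, consensus_threshold))
    n_cls = sum(r.classified for r in records)
    logger.info("annotated %d/%d bins with a consensus classification",
                n_cls, len(records))
    return records


def records_to_frame(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Flatten annotation records into one row per candidate (or per bin)."""
    rows = []
    for r in records:
        base = {"bin_id": r.bin_id, "mz": r.mz, "mode": r.mode,
                "consensus_lineage": ";".join(r.consensus_lineage),
                "consensus_depth": r.consensus_depth}
        if r.candidates.empty:
            rows.append({**base, "formula": "", "adduct": "",
                         "theoretical_mz": np.nan, "ppm_error": np.nan,
                         "compound_ids": "", "source": ""})
        else:
            for _, c in r.candidates.iterrows():
                rows.append({**base, "formula": c["formula"], "adduct": c["adduct"],
                             "theoretical_mz": c["theoretical_mz"],
                             "ppm_error": c["ppm_error"],
                             "compound_ids": ";".join(c["compound_ids"]),
                             "source": c["source"]})
    return pd.DataFrame(rows)


def composition_summary(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Bin counts per taxonomy term at each level (Sankey-ready).

    A bin contributes to every term along its consensus lineage; bins with no
    consensus appear under an explicit "unclassified" bucket at level 0.
    """
    counter: Counter[tuple[int, str]] = Counter()
    for r in records:
        if not r.classified:
            counter[(0, "unclassified")] += 1
        for level, term in enumerate(r.consensus_lineage):
            counter[(level, term)] += 1
    rows = [{"level": lv, "term": term, "count": n}
            for (lv, term), n in sorted(counter.items())]
    return pd.DataFrame(rows, columns=["level", "term", "count"])
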