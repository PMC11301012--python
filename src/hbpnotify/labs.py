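"""Laboratory panel flagging and roll-up into five abnormality categories.

Each analyte is compared against an inclusive reference interval (sex-specific
where defined); out-of-range analytes roll up into the five categories used in
the co-occurrence analysis: blood sugar, renal, lipid, hematological, liver.

The category composition is configuration, not dogma: renal is
creatinine/BUN; liver is AST/ALT; hematological is hemoglobin, platelets,
leukocytes, plus the cell-morphology rule; blood sugar is the glucose analyte
alone. Uric acid, sodium and CRP are flagged but map to no category by
default. Lipid abnormality arrives as a precomputed boolean (no lipid
thresholds are part of the reference table); the panel carries it through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CATEGORIES = ("blood_sugar", "renal", "lipid", "hematological", "liver")

#: Analytes contributing to each category (lipid is a pass-through boolean;
#: hematological additionally includes the abnormal-cells morphology rule).
DEFAULT_CATEGORY_MAP: dict[str, tuple[str, ...]] = {
    "blood_sugar": ("blood_sugar",),
    "renal": ("creatinine", "bun"),
    "lipid": (),
    "hematological": ("hemoglobin", "platelets", "leukocytes"),
    "liver": ("ast", "alt"),
}

NUMERIC_ANALYTES = (
    "crp",
    "hemoglobin",
    "platelets",
    "leukocytes",
    "blood_sugar",
    "ast",
    "alt",
    "creatinine",
    "bun",
    "uric_acid",
    "sodium",
)


@dataclass(frozen=True)
class ReferenceRange:
    """Inclusive interval for one analyte; a ``None`` bound is open."""

    analyte: str
    sex: str  # "male", "female" or "both"
    low: float | None
    high: float | None

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ValueError(f"{self.analyte}: low > high")


class RangeRegistry:
    """Reference ranges keyed by (analyte, sex), loaded from YAML config."""

    def __init__(self, ranges: Mapping[str, Mapping[str, ReferenceRange]], erythroblast_limit: int = 30):
        self._ranges = {k: dict(v) for k, v in ranges.items()}
        self.erythroblast_limit = erythroblast_limit

    @classmethod
    def from_yaml(cls, source=None) -> "RangeRegistry":
        """Load from a YAML file path, or the packaged defaults if omitted."""
        if source is None:
            text = (
                resources.files("hbpnotify.data")
                .joinpath("reference_ranges.yaml")
                .read_text()
            )
        else:
            with open(source) as fh:
                text = fh.read()
        raw = yaml.safe_load(text)
        ranges: dict[str, dict[str, ReferenceRange]] = {}
        for analyte, by_sex in raw["analytes"].items():
            ranges[analyte] = {
                sex: ReferenceRange(analyte, sex, spec["low"], spec["high"])
                for sex, spec in by_sex.items()
            }
        return cls(ranges, int(raw.get("erythroblast_limit_per_200", 30)))

    def lookup(self, analyte: str, sex: str) -> ReferenceRange:
        if analyte not in self._ranges:
            raise KeyError(f"unknown analyte {analyte!r}")
        by_sex = self._ranges[analyte]
        if sex in by_sex:
            return by_sex[sex]
        if "both" in by_sex:
            return by_sex["both"]
        raise KeyError(f"no range for analyte {analyte!r}, sex {sex!r}")

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(self._ranges)


_default_registry: RangeRegistry | None = None


def default_ranges() -> RangeRegistry:
    global _default_registry
    if _default_registry is None:
        _default_registry = RangeRegistry.from_yaml()
    return _default_registry


@dataclass(frozen=True)
class LabPanel:
    """One participant's blood panel. Any numeric analyte may be missing
    (``None``); missing values never count as normal — they are reported as
    explicitly missing and contribute no abnormality."""

    participant_id: str
    sex: str
    crp: float | None = None
    hemoglobin: float | None = None
    platelets: float | None = None
    leukocytes: float | None = None
    blood_sugar: float | None = None
    ast: float | None = None
    alt: float | None = None
    creatinine: float | None = None
    bun: float | None = None
    uric_acid: float | None = None
    sodium: float | None = None
    blast_cells_present: bool = False
    multiple_atypical_cells: bool = False
    erythroblasts_per_200: int = 0
    lipid_abnormal: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        for name in NUMERIC_ANALYTES:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.erythroblasts_per_200 < 0:
            raise ValueError("erythroblasts_per_200 must be >= 0")


@dataclass(frozen=True)
class CategoryFlags:
    """The five abnormality-category booleans used in the co-occurrence
    analysis."""

    blood_sugar: bool
    renal: bool
    lipid: bool
    hematological: bool
    liver: bool

    @staticmethod
    def field_order() -> tuple[str, ...]:
        return CATEGORIES

    def as_dict(self) -> dict[str, bool]:
        return {c: getattr(self, c) for c in CATEGORIES}


def flag_analyte(
    analyte: str,
    value: float | None,
    sex: str,
    ranges: RangeRegistry | None = None,
) -> str:
    """Classify one analyte value as 'low'/'normal'/'high'/'missing'.

    Bounds are inclusive: a value exactly at either bound is normal.
    """
    ranges = ranges or default_ranges()
    rng = ranges.lookup(analyte, sex)  # raises on unknown analyte
    if value is None:
        return "missing"
    if rng.low is not None and value < rng.low:
        return "low"
    if rng.high is not None and value > rng.high:
        return "high"
    return "normal"


def flag_abnormal_cells(panel: LabPanel, ranges: RangeRegistry | None = None) -> bool:
    """Cell-morphology rule: blast cells, multiple atypical cells, or more
    than 30 erythroblasts per 200 nucleated cells (strict inequality)."""
    limit = (ranges or default_ranges()).erythroblast_limit
    return (
        panel.blast_cells_present
        or panel.multiple_atypical_cells
        or panel.erythroblasts_per_200 > limit
    )


def categorize(
    panel: LabPanel,
    ranges: RangeRegistry | None = None,
    category_map: Mapping[str, tuple[str, ...]] | None = None,
) -> CategoryFlags:
    """Roll a panel up into the five category flags.

    A category is abnormal iff any mapped analyte is out of range (or, for
    hematological, the morphology rule fires). Missing analytes contribute
    false, with a log note.
    """
    ranges = ranges or default_ranges()
    category_map = category_map or DEFAULT_CATEGORY_MAP
    out: dict[str, bool] = {}
    for cat in CATEGORIES:
        abnormal = False
        for analyte in category_map.get(cat, ()):
            status = flag_analyte(analyte, getattr(panel, analyte), panel.sex, ranges)
            if status == "missing":
                logger.info(
                    "participant %s: %s missing, counted as not abnormal for %s",
                    panel.participant_id,
                    analyte,
                    cat,
                )
            elif status != "normal":
                abnormal = True
        out[cat] = abnormal
    out["hematological"] = out["hematological"] or flag_abnormal_cells(panel, ranges)
    out["lipid"] = out["lipid"] or panel.lipid_abnormal
    return CategoryFlags(**out)


# ---------------------------------------------------------------------------
# CSV interfaces

LABS_CSV_COLUMNS = [
    "participant_id",
    "sex",
    *NUMERIC_ANALYTES,
    "blast_cells",
    "atypical_cells",
    "erythroblasts_per_200",
    "lipid_abnormal",
]


def read_labs_csv(path) -> list[LabPanel]:
    """Read a labs CSV into panels; empty cells become missing analytes."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(LABS_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"labs CSV missing columns: {sorted(missing)}")
    panels = []
    for row in df.itertuples():
        numeric = {
            name: (None if pd.isna(getattr(row, name)) else float(getattr(row, name)))
            for name in NUMERIC_ANALYTES
        }
        panels.append(
            LabPanel(
                participant_id=row.participant_id,
                sex=row.sex,
                blast_cells_present=bool(row.blast_cells),
                multiple_atypical_cells=bool(row.atypical_cells),
                erythroblasts_per_200=int(row.erythroblasts_per_200),
                lipid_abnormal=bool(row.lipid_abnormal),
                **numeric,
            )
        )
    return panels


def flags_frame(
    panels: list[LabPanel],
    ranges: RangeRegistry | None = None,
    category_map: Mapping[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Category flags for many panels: participant_id + five boolean columns."""
    rows = []
    for panel in panels:
        flags = categorize(panel, ranges, category_map)
        rows.append({"participant_id": panel.participant_id, **flags.as_dict()})
    return pd.DataFrame(rows, columns=["participant_id", *CATEGORIES])
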