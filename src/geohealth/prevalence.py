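"""Multi-level disease prevalence from claims.

ICD-10 codes are organized as chapter (level 1, e.g. I00-I99) > block
(level 2, e.g. I10-I1A) > 3-character category (level 3, e.g. I10). Claims
codes are truncated to their category and rolled up along the hierarchy;
prevalence in a region-year is the share of distinct patients carrying any
code in the group among distinct patients with at least one visit recorded
in that region-year.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger("geohealth")

_CATEGORY_RE = re.compile(r"^[A-Za-z][0-9][0-9A-Za-z]")

def builtin_chapter_table() -> pd.DataFrame:
    """A small real ICD-10 chapter/block table for documentation examples.

    Covers the chapters this package's examples discuss (neoplasms;
    endocrine/metabolic; circulatory; pregnancy; perinatal; symptoms and
    ill-defined causes) and a handful of their blocks. Analyses always use
    the hierarchy table supplied alongside the claims; this table exists so
    the examples can name real groups without an external download.
    """
    rows = [
        ("C00-D49", "", 1, "Neoplasms"),
        ("E00-E89", "", 1, "Endocrine, nutritional and metabolic diseases"),
        ("I00-I99", "", 1, "Diseases of the circulatory system"),
        ("O00-O9A", "", 1, "Pregnancy, childbirth and the puerperium"),
        ("P00-P96", "", 1, "Certain conditions originating in the perinatal period"),
        ("R00-R99", "", 1, "Symptoms, signs and abnormal findings"),
        ("E08-E13", "E00-E89", 2, "Diabetes mellitus"),
        ("E40-E46", "E00-E89", 2, "Malnutrition"),
        ("E65-E68", "E00-E89", 2, "Overweight, obesity and other hyperalimentation"),
        ("E70-E88", "E00-E89", 2, "Metabolic disorders"),
        ("I05-I09", "I00-I99", 2, "Chronic rheumatic heart diseases"),
        ("I10-I1A", "I00-I99", 2, "Hypertensive diseases"),
        ("I20-I25", "I00-I99", 2, "Ischemic heart diseases"),
        ("I26-I28", "I00-I99", 2, "Pulmonary heart disease"),
        ("I60-I69", "I00-I99", 2, "Cerebrovascular diseases"),
    ]
    return pd.DataFrame(rows, columns=["code", "parent", "level", "description"])


@dataclass
class IcdHierarchy:
    """code -> (parent, level) lookup over a 3-level hierarchy table."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"code", "parent", "level"}
        if not required.issubset(t.columns):
            raise ValueError(f"hierarchy table needs columns {sorted(required)}")
        self._parent = dict(zip(t["code"], t["parent"]))
        self._level = dict(zip(t["code"], t["level"].astype(int)))
        # validate: acyclic chains, consistent levels along paths
        for code, lvl in self._level.items():
            node, steps = code, 0
            while self._parent.get(node, "") != "" and steps <= 3:
                parent = self._parent[node]
                if parent not in self._level:
                    raise ValueError(f"{node} has unknown parent {parent}")
                if self._level[parent] != self._level[node] - 1:
                    raise ValueError(
                        f"level inconsistency: {node} (level {self._level[node]}) "
                        f"under {parent} (level {self._level[parent]})"
                    )
                node, steps = parent, steps + 1
            if steps > 3:
                raise ValueError(f"cycle or overlong chain at {code}")
            if lvl > 1 and self._parent.get(code, "") == "":
                raise ValueError(f"non-top code {code} has no parent")

    def __contains__(self, code: str) -> bool:
        return code in self._level

    def ancestry(self, category: str) -> list[tuple[str, int]]:
        """(group, level) for the category itself and its ancestors."""
        out = [(category, self._level[category])]
        node = category
        while self._parent.get(node, "") != "":
            node = self._parent[node]
            out.append((node, self._level[node]))
        return out

    def groups_at_level(self, level: int) -> list[str]:
        return sorted(c for c, l in self._level.items() if l == level)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def truncate_to_category(code: str) -> str:
    """First three characters of an ICD-10 code, uppercased ('E11.9' -> 'E11')."""
    code = str(code).strip()
    if not _CATEGORY_RE.match(code):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return code[:3].upper()


def rollup(category: str, hierarchy: IcdHierarchy) -> set[tuple[str, int]]:
    """The category (level 3), its block (level 2) and chapter (level 1)."""
    if category not in hierarchy:
        raise KeyError(f"category {category!r} not in hierarchy")
    return set(hierarchy.ancestry(category))


def estimate_prevalence(
    claims: pd.DataFrame, hierarchy: IcdHierarchy, level: int
) -> pd.DataFrame:
    """Region-year prevalence of every ICD group at one hierarchy level.

    denominator(region, year) = distinct patients with >= 1 visit in that
    region-year; numerator(group) = distinct patients among them with >= 1
    code rolling up to the group. Groups with zero numerator are emitted
    with prevalence 0; region-years with zero denominator are omitted.
    Codes whose category is absent from the hierarchy are excluded and
    reported in the log with a count.

    Returns (region_id, year, icd_group, level, numerator, denominator,
    prevalence).
    """
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    df = claims.copy()
    df["year"] = pd.to_datetime(df["date"]).dt.year

    denom = (
        df.groupby(["region_id", "year"])["patient_id"]
        .nunique()
        .rename("denominator")
    )

    coded = df[df["icd_code"].astype(str).str.len() > 0].copy()
    if not coded.empty:
        # truncate via a per-unique-code lookup (claims repeat few codes)
        cat_of = {c: truncate_to_category(c) for c in coded["icd_code"].unique()}
        coded["category"] = coded["icd_code"].map(cat_of)
        known = coded["category"].isin(set(hierarchy.table["code"]))
        n_unmapped = int((~known).sum())
        if n_unmapped:
            examples = sorted(coded.loc[~known, "category"].unique())[:10]
            log.warning(
                "%d claim rows with categories not in hierarchy excluded "
                "from prevalence (e.g. %s)", n_unmapped, examples,
            )
        coded = coded[known]
        group_of = {
            cat: {lvl: grp for grp, lvl in hierarchy.ancestry(cat)}
            for cat in coded["category"].unique()
        }
        coded["icd_group"] = coded["category"].map(
            lambda c: group_of[c].get(level, None)
        )
        coded = coded.dropna(subset=["icd_group"])

    groups = hierarchy.groups_at_level(level)
    if coded.empty:
        numer = pd.DataFrame(columns=["region_id", "year", "icd_group", "numerator"])
    else:
        numer = (
            coded.groupby(["region_id", "year", "icd_group"])["patient_id"]
            .nunique()
            .rename("numerator")
            .reset_index()
        )

    base = denom.reset_index()
    full = base.merge(pd.DataFrame({"icd_group": groups}), how="cross")
    out = full.merge(numer, on=["region_id", "year", "icd_group"], how="left")
    out["numerator"] = out["numerator"].fillna(0).astype(int)
    out["denominator"] = out["denominator"].astype(int)
    out = out[out["denominator"] > 0]
    out["level"] = level
    out["prevalence"] = out["numerator"] / out["denominator"]
    cols = ["region_id", "year", "icd_group", "level",
            "numerator", "denominator", "prevalence"]
    return out[cols].sort_values(["region_id", "year", "icd_group"]).reset_index(drop=True)


def prevalence_panel(prev: pd.DataFrame, group: str) -> pd.Series:
    """One group's prevalence as a Series indexed by (region_id, year)."""
    sub = prev[prev["icd_group"] == group]
    if sub.empty:
        raise KeyError(f"group {group!r} absent from prevalence table")
    return sub.set_index(["region_id", "year"])["prevalence"].sort_index()


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_prevalence(prev: pd.DataFrame, path) -> None:
    prev.to_csv(path, index=False)


def read_prevalence(path) -> pd.DataFrame:
    return pd.read_csv(path)
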