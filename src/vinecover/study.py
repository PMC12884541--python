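"""Okanagan vineyard cover-crop study: packaged inputs and reproduction.

The field screening scored candidate cover crops at two organic vineyards
(CFF, Covert Family Farm Estate; KOW, Kalala Organic Estate Winery) in two
floor positions (in-row, under the trellis; inter-row, the alley) and two
life cycles (annual, perennial).  Site-specific measurements are dry
biomass (kg/ha) and ground coverage class; the remaining criteria are
shared ordinal scores (fruiting-zone interference 1-3 in-row only,
invasiveness risk 1-3, pest sensitivity 1-3, drought tolerance 1-3, winter
hardiness 1-7, traffic tolerance 1-2 inter-row only).

This module packages those tables, the expert-derived criterion weights,
and the published relative-closeness scores as versioned fixtures, builds
the eight site x position x life-cycle decision matrices (annuals and
perennials are ranked separately: the published two-species in-row
perennial scores sum exactly to 1, which only a standalone two-alternative
run produces), and re-runs the ranking against the published values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .topsis import (
    BENEFIT,
    COST,
    CriterionSpec,
    DecisionMatrix,
    RankingResult,
    make_decision_matrix,
    rank_alternatives,
)

__all__ = [
    "SITES",
    "POSITIONS",
    "LIFE_CYCLES",
    "WEIGHT_CONTEXTS",
    "DIRECTIONS",
    "StudyKey",
    "StudyWeights",
    "CategoryReport",
    "ReproductionReport",
    "FixtureError",
    "load_table",
    "load_records",
    "study_weights",
    "weight_context_for",
    "assemble_matrix",
    "published_rankings",
    "reproduce",
]

SITES = ("CFF", "KOW")
POSITIONS = ("in_row", "inter_row")
LIFE_CYCLES = ("annual", "perennial")
WEIGHT_CONTEXTS = ("in_row", "inter_row_annual", "inter_row_perennial")

#: Optimisation direction of each criterion.  Reconstructed from criterion
#: semantics: more biomass/coverage/stress tolerance is better; interference
#: with the fruit zone, invasiveness and pest association are penalties.
DIRECTIONS = {
    "dry_biomass": BENEFIT,
    "ground_coverage": BENEFIT,
    "fruiting_zone_interference": COST,
    "invasiveness_risk": COST,
    "pest_sensitivity": COST,
    "drought_tolerance": BENEFIT,
    "winter_hardiness": BENEFIT,
    "traffic_tolerance": BENEFIT,
}

_TABLE_FILES = {
    "in_row": "table5_in_row.csv",
    "inter_row": "table6_inter_row.csv",
    "weights": "table7_weights.csv",
    "published": "published_rankings.csv",
}


class FixtureError(RuntimeError):
    """Packaged fixture is missing or fails its checksum."""


@dataclass(frozen=True)
class StudyKey:
    """One of the eight ranking cells: site x position x life cycle."""

    site: str
    position: str
    life_cycle: str

    def __post_init__(self):
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}")
        if self.life_cycle not in LIFE_CYCLES:
            raise ValueError(f"life_cycle must be one of {LIFE_CYCLES}")


@dataclass(frozen=True)
class StudyWeights:
    """Published criterion weights for one context, with the N/A set."""

    context: str
    weights: dict[str, float]
    not_applicable: frozenset[str]

    def renormalized(self) -> dict[str, float]:
        """Weights rescaled to sum exactly 1 (printed columns are rounded)."""
        total = sum(self.weights.values())
        return {k: v / total for k, v in self.weights.items()}


def _load_manifest() -> dict[str, str]:
    pkg = resources.files("vinecover") / "data"
    return json.loads((pkg / "manifest.json").read_text())


def _read_fixture(name: str) -> pd.DataFrame:
    pkg = resources.files("vinecover") / "data"
    fname = _TABLE_FILES[name]
    path = pkg / fname
    try:
        raw = path.read_bytes()
    except FileNotFoundError as e:
        raise FixtureError(f"fixture {fname} missing from package") from e
    manifest = _load_manifest()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != manifest[fname]:
        raise FixtureError(
            f"fixture {fname} checksum mismatch: {digest} != {manifest[fname]}"
        )
    import io

    return pd.read_csv(io.BytesIO(raw))


def load_table(name: str) -> pd.DataFrame:
    """Load a packaged fixture ('in_row', 'inter_row', 'weights', 'published')."""
    return _read_fixture(name)


def load_records(position: str) -> pd.DataFrame:
    """Per-species criterion scores for one floor position.

    Returns the verbatim transcription: 9 species in-row, 15 inter-row,
    with site-specific biomass/coverage columns and shared ordinal scores.
    """
    if position not in POSITIONS:
        raise ValueError(f"position must be one of {POSITIONS}")
    return _read_fixture(position)


def weight_context_for(position: str, life_cycle: str) -> str:
    """Map a ranking cell to its weight column (in-row shares one column)."""
    if position == "in_row":
        return "in_row"
    return f"inter_row_{life_cycle}"


def study_weights(context: str) -> StudyWeights:
    """Published expert-derived weights for one context."""
    if context not in WEIGHT_CONTEXTS:
        raise ValueError(f"context must be one of {WEIGHT_CONTEXTS}, got {context!r}")
    tab = _read_fixture("weights")
    weights, na = {}, set()
    for _, row in tab.iterrows():
        val = row[context]
        if pd.isna(val) or str(val).strip() == "N/A":
            na.add(row["criterion"])
        else:
            weights[row["criterion"]] = float(val)
    return StudyWeights(context=context, weights=weights, not_applicable=frozenset(na))


def assemble_matrix(key: StudyKey) -> DecisionMatrix:
    """Decision matrix for one ranking cell.

    Columns are the criteria applicable to the position (interference
    in-row only, traffic inter-row only), with the site's biomass and
    coverage measurements; weights come from the published table,
    renormalized over the applicable criteria.
    """
    records = load_records(key.position)
    records = records[records["life_cycle"] == key.life_cycle]
    sw = study_weights(weight_context_for(key.position, key.life_cycle))
    w = sw.renormalized()
    site = key.site.lower()
    columns = {"dry_biomass": f"biomass_{site}", "ground_coverage": f"coverage_{site}"}
    for crit in w:
        if crit not in columns:
            columns[crit] = crit
    criteria = tuple(
        CriterionSpec(name=crit, direction=DIRECTIONS[crit], weight=w[crit])
        for crit in w
    )
    values = records[[columns[c.name] for c in criteria]].to_numpy(dtype=float)
    return make_decision_matrix(values, tuple(records["name"]), criteria)


def published_rankings(key: StudyKey) -> pd.Series:
    """Published relative-closeness scores for one cell (descending order)."""
    tab = _read_fixture("published")
    sel = tab[
        (tab["site"] == key.site)
        & (tab["position"] == key.position)
        & (tab["life_cycle"] == key.life_cycle)
    ]
    return sel.set_index("name")["rc"]


@dataclass(frozen=True)
class CategoryReport:
    """Computed vs published scores for one ranking cell."""

    key: StudyKey
    table: pd.DataFrame  # rc_computed, rc_published, abs_diff, rank_computed, rank_published
    max_abs_diff: float
    rank_matches: int
    n: int
    spearman: float
    top_computed: str
    top_published: str

    @property
    def top_agrees(self) -> bool:
        return self.top_computed == self.top_published


@dataclass(frozen=True)
class ReproductionReport:
    """All four ranking cells for one site."""

    site: str
    categories: tuple[CategoryReport, ...]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": c.key.position,
                    "life_cycle": c.key.life_cycle,
                    "n": c.n,
                    "max_abs_diff": c.max_abs_diff,
                    "rank_matches": c.rank_matches,
                    "spearman": c.spearman,
                    "top_computed": c.top_computed,
                    "top_published": c.top_published,
                    "top_agrees": c.top_agrees,
                }
                for c in self.categories
            ]
        )


def _category_report(key: StudyKey, result: RankingResult) -> CategoryReport:
    pub = published_rankings(key)
    comp = pd.Series(result.rc, index=list(result.alternative_labels))
    tab = pd.DataFrame({"rc_computed": comp, "rc_published": pub})
    tab["abs_diff"] = (tab["rc_computed"] - tab["rc_published"]).abs()
    tab["rank_computed"] = tab["rc_computed"].rank(ascending=False, method="first").astype(int)
    tab["rank_published"] = tab["rc_published"].rank(ascending=False, method="first").astype(int)
    if len(tab) > 2:
        rho = float(spearmanr(tab["rc_computed"], tab["rc_published"]).statistic)
    else:
        # Spearman is degenerate for 2 alternatives; agreement is +-1
        rho = 1.0 if (tab["rank_computed"] == tab["rank_published"]).all() else -1.0
    return CategoryReport(
        key=key,
        table=tab.sort_values("rank_published"),
        max_abs_diff=float(tab["abs_diff"].max()),
        rank_matches=int((tab["rank_computed"] == tab["rank_published"]).sum()),
        n=len(tab),
        spearman=rho,
        top_computed=tab["rank_computed"].idxmin(),
        top_published=tab["rank_published"].idxmin(),
    )


def reproduce(site: str, invert_costs: bool = False) -> ReproductionReport:
    """Re-run the ranking for all four cells of a site against publication.

    Disagreements are reported, never raised.
    """
    reports = []
    for position in POSITIONS:
        for cycle in LIFE_CYCLES:
            key = StudyKey(site, position, cycle)
            result = rank_alternatives(assemble_matrix(key), invert_costs=invert_costs)
            reports.append(_category_report(key, result))
    return ReproductionReport(site=site, categories=tuple(reports))
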