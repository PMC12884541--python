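"""Criterion-removal sensitivity analysis.

Re-runs a ranking with one or more criteria removed -- their weight set to
zero and the remaining weights renormalized proportionally -- and reports
per-alternative shifts in relative closeness and rank.  The study's own
experiment removes the dominant "risk of being invasive" criterion to ask
how much the rankings lean on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .study import StudyKey, assemble_matrix
from .topsis import CriterionSpec, DecisionMatrix, rank_alternatives

__all__ = ["RankShiftReport", "drop_criteria", "drop_matrix_criteria", "sensitivity_run"]


@dataclass(frozen=True)
class RankShiftReport:
    """Per-alternative rc/rank shifts after criterion removal.

    ``delta_rank`` is ``rank_base - rank_modified``: positive means the
    alternative improved (moved toward rank 1).
    """

    removed_criteria: tuple[str, ...]
    renormalized_weights: dict[str, float]
    table: pd.DataFrame  # rc_base, rc_modified, delta_rc, rank_base, rank_modified, delta_rank

    def delta_rc_of(self, label: str) -> float:
        return float(self.table.loc[label, "delta_rc"])

    def delta_rank_of(self, label: str) -> int:
        return int(self.table.loc[label, "delta_rank"])


def drop_criteria(criteria, names) -> tuple[CriterionSpec, ...]:
    """Remove named criteria; renormalize remaining weights proportionally."""
    criteria = tuple(criteria)
    names = set(names)
    known = {c.name for c in criteria}
    unknown = names - known
    if unknown:
        raise KeyError(f"unknown criterion name(s): {sorted(unknown)}")
    kept = [c for c in criteria if c.name not in names]
    if not kept:
        raise ValueError("cannot remove every criterion")
    total = sum(c.weight for c in kept)
    if total <= 0:
        raise ValueError("remaining criteria all have zero weight")
    return tuple(
        CriterionSpec(c.name, c.direction, c.weight / total) for c in kept
    )


def drop_matrix_criteria(dm: DecisionMatrix, names) -> DecisionMatrix:
    """Delete the named criterion columns and renormalize the rest."""
    kept_specs = drop_criteria(dm.criteria, names)
    keep_idx = [
        j for j, c in enumerate(dm.criteria) if c.name in {k.name for k in kept_specs}
    ]
    return DecisionMatrix(
        values=dm.values[:, keep_idx],
        alternative_labels=dm.alternative_labels,
        criteria=kept_specs,
    )


def sensitivity_run(
    key: StudyKey, removed_names, invert_costs: bool = False,
    weights_override: dict[str, float] | None = None,
) -> RankShiftReport:
    """Baseline vs criterion-removed ranking for one study cell.

    ``weights_override`` substitutes externally supplied post-removal
    weights (e.g. re-elicited ones) for the proportional renormalization.
    """
    base_dm = assemble_matrix(key)
    base = rank_alternatives(base_dm, invert_costs=invert_costs)
    mod_dm = drop_matrix_criteria(base_dm, removed_names)
    if weights_override is not None:
        total = sum(weights_override.values())
        specs = tuple(
            CriterionSpec(c.name, c.direction, weights_override[c.name] / total)
            for c in mod_dm.criteria
        )
        mod_dm = DecisionMatrix(mod_dm.values, mod_dm.alternative_labels, specs)
    mod = rank_alternatives(mod_dm, invert_costs=invert_costs)
    tab = pd.DataFrame(
        {
            "rc_base": base.rc,
            "rc_modified": mod.rc,
            "rank_base": base.rank,
            "rank_modified": mod.rank,
        },
        index=list(base.alternative_labels),
    )
    tab["delta_rc"] = tab["rc_modified"] - tab["rc_base"]
    tab["delta_rank"] = tab["rank_base"] - tab["rank_modified"]
    return RankShiftReport(
        removed_criteria=tuple(removed_names),
        renormalized_weights={c.name: c.weight for c in mod_dm.criteria},
        table=tab,
    )
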