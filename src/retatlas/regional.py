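"""Fovea versus periphery: per-type differential expression and proportions.

Types are compared between regions only when both cohorts have at least 20
cells; differential genes are those with |logFC| ≥ 1 (natural log) at
adjusted p < 0.001. Cell-type proportions are tabulated within class per
donor, with median/IQR summaries across donors per region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import de_test
from .io import REGIONS, ValidationError
from .preprocess import NormalizedMatrix


@dataclass
class RegionalDEReport:
    """Per-type regional DE summary plus full DE tables for tested types."""

    summary: pd.DataFrame                 # type, n_fovea, n_periphery, tested, n_de
    tables: dict[str, pd.DataFrame]

    def tested_types(self) -> list[str]:
        return list(self.summary.loc[self.summary["tested"], "type"])


def regional_de(
    norm: NormalizedMatrix,
    type_labels,
    region_labels,
    min_cells: int = 20,
    min_lfc: float = 1.0,
    alpha: float = 0.001,
    min_pct: float = 0.0,
) -> RegionalDEReport:
    """Count DE genes between foveal and peripheral cohorts of each type.

    Only types with at least ``min_cells`` cells in *both* regions are
    tested (the boundary is inclusive: exactly 20 in each region tests).
    """
    types = np.asarray(type_labels, dtype=object)
    regions = np.asarray(region_labels, dtype=object)
    unknown = set(regions) - set(REGIONS)
    if unknown:
        raise ValidationError(f"unknown region labels {sorted(unknown)}")
    if len(types) != norm.n_cells or len(regions) != norm.n_cells:
        raise ValidationError("labels do not cover all cells")

    rows, tables = [], {}
    for t in sorted(set(types)):
        fov = (types == t) & (regions == "fovea")
        per = (types == t) & (regions == "periphery")
        n_f, n_p = int(fov.sum()), int(per.sum())
        tested = n_f >= min_cells and n_p >= min_cells
        n_de = None
        if tested:
            res = de_test(norm, fov, per, min_pct=min_pct, min_lfc=min_lfc)
            hits = res[res["tested"] & (res["logFC"].abs() >= min_lfc) & (res["p_adj"] < alpha)]
            tables[str(t)] = hits.reset_index(drop=True)
            n_de = len(hits)
        rows.append({"type": str(t), "n_fovea": n_f, "n_periphery": n_p,
                     "tested": tested, "n_de": n_de})
    return RegionalDEReport(summary=pd.DataFrame(rows), tables=tables)


@dataclass
class ProportionTable:
    """Within-class type proportions per donor, with cross-donor summaries."""

    per_donor: pd.DataFrame   # class, region, donor, type, n_cells, fraction
    summary: pd.DataFrame     # class, region, type, median, q1, q3


def proportions(type_labels, class_labels, metadata: pd.DataFrame) -> ProportionTable:
    """Per-donor within-class type fractions and their median/IQR by region.

    ``metadata`` must carry region and donor for every labelled cell, in
    the same order as the label arrays.
    """
    frame = pd.DataFrame({
        "type": np.asarray(type_labels, dtype=object),
        "class": np.asarray(class_labels, dtype=object),
        "region": metadata["region"].to_numpy(),
        "donor": metadata["donor"].to_numpy(),
    })
    counts = (
        frame.groupby(["class", "region", "donor", "type"], sort=True)
        .size().rename("n_cells").reset_index()
    )
    totals = counts.groupby(["class", "region", "donor"])["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals

    # complete the per-donor grid with zeros for absent types of a class
    full = []
    for (cls, region, donor), grp in counts.groupby(["class", "region", "donor"]):
        class_types = sorted(set(frame.loc[frame["class"] == cls, "type"]))
        missing = set(class_types) - set(grp["type"])
        full.append(grp)
        if missing:
            full.append(pd.DataFrame({
                "class": cls, "region": region, "donor": donor,
                "type": sorted(missing), "n_cells": 0, "fraction": 0.0,
            }))
    per_donor = pd.concat(full, ignore_index=True).sort_values(
        ["class", "region", "donor", "type"], ignore_index=True
    )
    summary = (
        per_donor.groupby(["class", "region", "type"])["fraction"]
        .agg(median="median", q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return ProportionTable(per_donor=per_donor, summary=summary)


def ratio_summary(prop: ProportionTable, numerator_types, denominator_types) -> pd.DataFrame:
    """Pooled-cell ratio of two type groups per region, plus per-donor ratios.

    A zero-cell denominator yields an infinite ratio with ``degenerate=True``.
    """
    num = set(map(str, numerator_types))
    den = set(map(str, denominator_types))
    if not num or not den:
        raise ValidationError("both type groups must be non-empty")
    tab = prop.per_donor
    rows = []
    for region, grp in tab.groupby("region"):
        n_num = int(grp.loc[grp["type"].isin(num), "n_cells"].sum())
        n_den = int(grp.loc[grp["type"].isin(den), "n_cells"].sum())
        pooled = np.inf if n_den == 0 else n_num / n_den
        donor_ratios = {}
        for donor, dgrp in grp.groupby("donor"):
            dn = int(dgrp.loc[dgrp["type"].isin(num), "n_cells"].sum())
            dd = int(dgrp.loc[dgrp["type"].isin(den), "n_cells"].sum())
            donor_ratios[donor] = np.inf if dd == 0 else dn / dd
        rows.append({
            "region": region, "n_numerator": n_num, "n_denominator": n_den,
            "ratio": pooled, "degenerate": n_den == 0,
            "donor_ratios": donor_ratios,
        })
    return pd.DataFrame(rows)
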