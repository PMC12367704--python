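"""Result surfaces: window-length sweep, spatio-spectral group summaries and
connectivity edge-direction tables.

Group means are reported both at window level (every window counts once) and
at subject level (each subject contributes the mean of its windows), since
the two can disagree when window counts differ between subjects.  Direction
labels are the sign of (SCZ mean - HC mean); standardized effect sizes are
Cohen's d with the pooled window-level standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_BANDS,
    DEFAULT_BOUNDS,
    ConfigurationError,
    InputError,
)
from .features import (
    FuzEnParams,
    extract_features,
    feature_columns,
    parse_feature_name,
)
from .modeling import CVResult, ModelConfig, cross_validate, make_folds
from .selection import RFETrace, export_subset

#: Standard 10-20 region membership for the 16-channel montage.
DEFAULT_REGIONS: dict[str, str] = {
    "F3": "frontal", "F4": "frontal", "F7": "frontal", "F8": "frontal",
    "C3": "central", "C4": "central", "Cz": "central",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
    "P3": "parietal", "P4": "parietal", "Pz": "parietal",
    "O1": "occipital", "O2": "occipital",
}


def window_sweep(
    recordings,
    window_lengths=(1.0, 2.0, 3.0, 4.0, 5.0, 6.0),
    mc: ModelConfig = None,
    n_folds: int = 10,
    seed: int = 0,
    unit: str = "window",
    bands=DEFAULT_BANDS,
    bounds=DEFAULT_BOUNDS,
    fuzen_params: FuzEnParams = FuzEnParams(),
    families=("RP", "FuzEn", "PLI"),
) -> pd.DataFrame:
    """Run extract -> cross-validate once per window length.

    Returns one row per length: window_s, n_rows, n_features, accuracy
    mean and sd (percent).
    """
    mc = mc or ModelConfig()
    duration = min(rec.duration_s for rec in recordings)
    for w in window_lengths:
        if w > duration:
            raise ConfigurationError(
                f"window of {w} s exceeds the shortest recording ({duration} s)"
            )
    rows = []
    for w in window_lengths:
        table = extract_features(
            recordings, window_length_s=w, bands=bands, bounds=bounds,
            fuzen_params=fuzen_params, families=families,
        )
        folds = make_folds(table, n_folds=n_folds, seed=seed, unit=unit)
        res = cross_validate(table, mc, folds)
        rows.append(
            {"window_s": w, "n_rows": len(table),
             "n_features": len(feature_columns(table)),
             "accuracy_mean": res.mean("accuracy"),
             "accuracy_sd": res.sd("accuracy")}
        )
    return pd.DataFrame(rows)


@dataclass
class GroupDiffSummary:
    """Per-feature group means and directions plus their aggregations."""

    per_feature: pd.DataFrame  # feature, family, band, site, means, d, direction
    crosstab: pd.DataFrame  # family x band counts of summarized features
    pli_edges: pd.DataFrame  # one row per summarized PLI feature
    region_proportions: pd.DataFrame  # band x region edge-endpoint shares
    regions: dict[str, str] = field(default_factory=dict)


def summarize_groups(
    table: pd.DataFrame,
    subset: list[str] | None = None,
    regions: dict[str, str] = None,
) -> GroupDiffSummary:
    """Group-difference summary over all features or a selected subset.

    The PLI edge list labels each edge with its endpoint regions and
    direction; region proportions count edge endpoints per region within
    each band (each edge contributes both endpoints).
    """
    regions = dict(DEFAULT_REGIONS if regions is None else regions)
    cols = feature_columns(table)
    if subset is None:
        subset = cols
    else:
        unknown = [c for c in subset if c not in cols]
        if unknown:
            raise InputError(f"subset references unknown features {unknown[:5]}")
    groups = set(table["group"])
    if not {"HC", "SCZ"} <= groups:
        raise InputError(f"need both groups in the table, found {sorted(groups)}")

    is_scz = table["group"] == "SCZ"
    sub_means = table.groupby(["subject_id", "group"], sort=True)[
        list(subset)
    ].mean().reset_index()

    rows = []
    for name in subset:
        key = parse_feature_name(name)
        hc_vals = table.loc[~is_scz, name].to_numpy()
        scz_vals = table.loc[is_scz, name].to_numpy()
        hc_m, scz_m = float(hc_vals.mean()), float(scz_vals.mean())
        n1, n2 = len(hc_vals), len(scz_vals)
        pooled = np.sqrt(
            ((n1 - 1) * hc_vals.var(ddof=1) + (n2 - 1) * scz_vals.var(ddof=1))
            / max(n1 + n2 - 2, 1)
        )
        rows.append(
            {
                "feature": name,
                "family": key.family,
                "band": key.band,
                "site": "-".join(key.site),
                "hc_mean": hc_m,
                "scz_mean": scz_m,
                "hc_mean_subject": float(
                    sub_means.loc[sub_means["group"] == "HC", name].mean()
                ),
                "scz_mean_subject": float(
                    sub_means.loc[sub_means["group"] == "SCZ", name].mean()
                ),
                "cohen_d": float((scz_m - hc_m) / pooled) if pooled > 0 else 0.0,
                "direction": "SCZ>HC" if scz_m > hc_m else "SCZ<HC",
            }
        )
    per_feature = pd.DataFrame(
        rows,
        columns=["feature", "family", "band", "site", "hc_mean", "scz_mean",
                 "hc_mean_subject", "scz_mean_subject", "cohen_d", "direction"],
    )

    crosstab = export_subset(list(subset))

    pli = per_feature[per_feature["family"] == "PLI"].copy()
    if len(pli):
        sites = pli["site"].str.split("-", expand=True)
        pli["ch_a"], pli["ch_b"] = sites[0], sites[1]
        pli["region_a"] = pli["ch_a"].map(regions)
        pli["region_b"] = pli["ch_b"].map(regions)
    else:
        for col in ("ch_a", "ch_b", "region_a", "region_b"):
            pli[col] = pd.Series(dtype=str)
    pli_edges = pli.reset_index(drop=True)

    region_names = sorted(set(regions.values()))
    band_order = [b.name for b in DEFAULT_BANDS]
    prop_rows = []
    for band in [b for b in band_order if (pli_edges["band"] == b).any()]:
        sel = pli_edges[pli_edges["band"] == band]
        endpoints = pd.concat([sel["region_a"], sel["region_b"]])
        counts = endpoints.value_counts()
        total = counts.sum()
        prop_rows.append(
            {"band": band,
             **{r: counts.get(r, 0) / total for r in region_names}}
        )
    region_proportions = pd.DataFrame(
        prop_rows, columns=["band", *region_names]
    )
    return GroupDiffSummary(
        per_feature=per_feature,
        crosstab=crosstab,
        pli_edges=pli_edges,
        region_proportions=region_proportions,
        regions=regions,
    )


def render_reports(
    summary: GroupDiffSummary,
    out_dir,
    trace: RFETrace | None = None,
    cv: CVResult | None = None,
    sweep: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the tabular report files; returns {name: path}.

    Output is deterministic (fixed float formatting, stable row order), so
    re-running with the same seeds reproduces the files byte for byte.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create report directory {out_dir}: {exc}")
    ff = "%.10g"
    paths: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = out_dir / name
        df.to_csv(p, index=index, float_format=ff)
        paths[name] = p

    _write("group_summary.csv", summary.per_feature)
    _write("subset_crosstab.csv", summary.crosstab, index=True)
    _write(
        "pli_edges.csv",
        summary.pli_edges[
            [c for c in ("feature", "band", "ch_a", "ch_b", "region_a",
                         "region_b", "hc_mean", "scz_mean", "direction")
             if c in summary.pli_edges.columns]
        ],
    )
    _write("region_proportions.csv", summary.region_proportions)
    if sweep is not None:
        _write("window_sweep.csv", sweep)
    if trace is not None:
        trace.to_json(out_dir / "rfe.json")
        paths["rfe.json"] = out_dir / "rfe.json"
    if cv is not None:
        cv.to_json(out_dir / "cv.json")
        paths["cv.json"] = out_dir / "cv.json"
    log = out_dir / "run_log.txt"
    with open(log, "w") as fh:
        fh.write(
            f"features summarized: {len(summary.per_feature)}\n"
            f"pli edges: {len(summary.pli_edges)}\n"
            + (f"optimal subset size: {trace.optimal_size}\n" if trace else "")
            + (f"cv accuracy mean: {cv.mean('accuracy'):.10g}\n" if cv else "")
        )
    paths["run_log.txt"] = log
    return paths
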