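"""Cohort pipeline orchestration, group summaries, tables and figures.

Runs the full analysis over a directory (or in-memory cohort) of paired
pre/post RR recordings: adaptive ectopy filtering and quality gates, linear
HRV indices, embedding + recurrence quantification, and the surrogate-data
nonlinearity test; then summarizes per moment and (optionally) per
prior-infarction stratum, with Clopper-Pearson intervals on the proportion
of nonlinear series and Bonferroni-adjusted paired comparisons.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import hrv_linear, nl_test, preprocess, rqa
from .embedding import embed, select_embedding
from .preprocess import RRSeries

logger = logging.getLogger("nlhrv")

DEFAULT_CONFIG: Dict = {
    "density": 0.07,
    "rho": 0.01,
    "n_surrogates": 99,
    "statistics": ["DET", "LAM"],
    "method": "pwiaaft",
    "l_min": 2,
    "v_min": 2,
    "theiler_window": 1,
    "resample_rate": 3.0,
    "window_len": 300,
    "overlap": 0.5,
    "min_duration": 300.0,
    "max_replaced": 0.05,
    "filter_window": 10,
    "filter_z": 3.0,
    "seed": 0,
}


@dataclass
class CohortResult:
    """Per-record indices and classifications plus reproducible settings."""

    records: pd.DataFrame          # one row per (record, moment)
    excluded: pd.DataFrame         # records that failed the quality gates
    config: Dict
    metadata: Optional[pd.DataFrame] = None

    def summary(self, stratify_by: str = "none") -> pd.DataFrame:
        return summarize_groups(self.records, self.metadata, stratify_by)

    def nonlinear_proportions(self) -> pd.DataFrame:
        rows = []
        for (stat, moment), grp in self.records.groupby(["statistic", "moment"], dropna=False):
            sub = grp.dropna(subset=["nonlinear"])
            k = int(sub["nonlinear"].sum())
            n = len(sub)
            if n == 0:
                continue
            ci = nl_test.clopper_pearson(k, n)
            rows.append(
                {"statistic": stat, "moment": moment, "k": k, "n": n,
                 "percent": ci.point, "ci_low": ci.lower, "ci_high": ci.upper}
            )
        return pd.DataFrame(rows)


def load_config(path: Union[str, Path, None] = None, **overrides) -> Dict:
    """Default parameters, optionally updated from a YAML file and kwargs."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(cfg) - {"input_dir", "output_dir"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    cfg.update(overrides)
    return cfg


def analyze_record(
    series: RRSeries, config: Dict, seed: int
) -> Tuple[Optional[dict], List[dict]]:
    """Process one recording; returns (base_row or None, per-statistic rows)."""
    filtered = preprocess.adaptive_ectopic_filter(
        series, window=config["filter_window"], z_threshold=config["filter_z"]
    )
    gate = preprocess.exclusion_gate(
        filtered, min_duration=config["min_duration"], max_replaced=config["max_replaced"]
    )
    base = {
        "record_id": series.record_id,
        "moment": series.moment,
        "n_beats": filtered.n_beats,
        "duration_s": filtered.total_duration,
        "replaced_fraction": filtered.replaced_fraction,
    }
    if not gate.included:
        base["excluded_reason"] = gate.reason
        return None, [base]

    li = hrv_linear.linear_indices(
        filtered,
        rate=config["resample_rate"],
        window_len=config["window_len"],
        overlap=config["overlap"],
    )
    for name in ("mean_nn", "sdnn", "sdsd", "lf_ms2", "hf_ms2", "lf_nu",
                 "hf_nu", "ln_lf", "ln_hf", "ln_lf_hf"):
        base[name] = getattr(li, name)

    params = select_embedding(filtered.intervals)
    base["m"], base["tau"] = params.m, params.tau
    det, lam = rqa.rqa_measures(
        embed(filtered.intervals, params.m, params.tau),
        density=config["density"], l_min=config["l_min"],
        v_min=config["v_min"], theiler_window=config["theiler_window"],
    )
    base["DET"], base["LAM"] = det, lam

    rows = []
    for stat in config["statistics"]:
        res = nl_test.NonlinearityTest(
            filtered,
            statistic=stat,
            method=config["method"],
            n_surrogates=config["n_surrogates"],
            rho=config["rho"],
            density=config["density"],
            l_min=config["l_min"],
            v_min=config["v_min"],
            theiler_window=config["theiler_window"],
            params=params,
        ).fit(seed=seed)
        row = dict(base)
        row.update(
            {"statistic": stat, "original_value": res.original_value,
             "rank": res.rank, "nonlinear": res.classified_nonlinear}
        )
        rows.append(row)
    return base, rows


def run_pipeline(
    records: Union[str, Path, Sequence[Tuple[RRSeries, RRSeries]]],
    config: Optional[Dict] = None,
    metadata: Optional[pd.DataFrame] = None,
    output_dir: Union[str, Path, None] = None,
    make_figures: bool = False,
) -> CohortResult:
    """Run the complete cohort analysis.

    ``records`` is either a directory of RR files (``<id>_pre.txt`` /
    ``<id>_post.txt``, with optional ``metadata.csv``) or a sequence of
    (pre, post) :class:`RRSeries` pairs.  The run is deterministic given the
    config seed: record ``i`` of the cohort uses seed ``seed + 100*i``.
    Failures of individual records are logged and the run continues.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)

    if isinstance(records, (str, Path)):
        records, metadata = _read_record_dir(Path(records), metadata)

    rows: List[dict] = []
    excluded: List[dict] = []
    for i, pair in enumerate(records):
        for series in pair:
            seed = (cfg["seed"] + 100 * i) % 2 ** 31
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    base, out = analyze_record(series, cfg, seed)
            except Exception as exc:  # keep going, report at the end
                logger.warning("record %s/%s failed: %s", series.record_id, series.moment, exc)
                excluded.append(
                    {"record_id": series.record_id, "moment": series.moment,
                     "excluded_reason": f"error: {exc}"}
                )
                continue
            if base is None:
                excluded.extend(out)
                logger.info("record %s/%s excluded: %s", series.record_id,
                            series.moment, out[0].get("excluded_reason"))
            else:
                rows.extend(out)
                logger.info("record %s/%s: m=%d tau=%d", series.record_id,
                            series.moment, base["m"], base["tau"])
    result = CohortResult(
        records=pd.DataFrame(rows),
        excluded=pd.DataFrame(excluded),
        config=cfg,
        metadata=metadata,
    )
    if output_dir is not None:
        write_outputs(result, Path(output_dir), make_figures=make_figures)
    return result


def _read_record_dir(path: Path, metadata: Optional[pd.DataFrame]):
    files = sorted(path.glob("*_pre.txt"))
    if not files:
        raise FileNotFoundError(f"no '*_pre.txt' recordings found in {path}")
    pairs = []
    for f in files:
        rid = f.name[: -len("_pre.txt")]
        pre = preprocess.read_rr(f, record_id=rid, moment="pre")
        post_path = path / f"{rid}_post.txt"
        if not post_path.exists():
            logger.warning("record %s has no post file; skipped", rid)
            continue
        post = preprocess.read_rr(post_path, record_id=rid, moment="post")
        pairs.append((pre, post))
    meta_path = path / "metadata.csv"
    if metadata is None and meta_path.exists():
        metadata = preprocess.read_metadata(meta_path)
    return pairs, metadata


INDEX_COLUMNS = ["mean_nn", "sdnn", "sdsd", "ln_lf", "ln_hf", "lf_nu",
                 "hf_nu", "ln_lf_hf", "DET", "LAM"]


def summarize_groups(
    records: pd.DataFrame,
    metadata: Optional[pd.DataFrame] = None,
    stratify_by: str = "none",
) -> pd.DataFrame:
    """Mean +/- SD per index, moment and stratum, with paired tests.

    Within-group pre/post comparisons use the paired t-test; with
    stratification the p-values are Bonferroni-adjusted for the number of
    strata.  Strata of fewer than 2 complete pairs are flagged and skipped.
    """
    df = records.drop_duplicates(subset=["record_id", "moment"]).copy()
    if stratify_by == "none":
        df["_stratum"] = "all"
    elif stratify_by == "prior_mi":
        if metadata is None:
            raise ValueError("stratification by prior_mi needs metadata")
        df = df.merge(metadata[["record_id", "prior_mi"]], on="record_id", how="left")
        df["_stratum"] = np.where(df["prior_mi"].astype(bool), "prior_mi", "no_prior_mi")
    else:
        raise ValueError(f"unknown stratification {stratify_by!r}")

    strata = sorted(df["_stratum"].unique())
    rows = []
    for stratum in strata:
        sub = df[df["_stratum"] == stratum]
        wide = sub.pivot_table(index="record_id", columns="moment", values=INDEX_COLUMNS)
        for index_name in INDEX_COLUMNS:
            if index_name not in {c[0] for c in wide.columns}:
                continue
            pre = wide.get((index_name, "pre"))
            post = wide.get((index_name, "post"))
            row = {"stratum": stratum, "index": index_name,
                   "n": int(sub["record_id"].nunique())}
            for moment, vals in (("pre", pre), ("post", post)):
                if vals is not None:
                    row[f"{moment}_mean"] = float(vals.mean())
                    row[f"{moment}_sd"] = float(vals.std())
            if pre is not None and post is not None:
                paired = pd.concat([pre, post], axis=1).dropna()
                if len(paired) >= 2:
                    t, p = nl_test.compare_paired_means(
                        paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy()
                    )
                    adj = float(nl_test.bonferroni_adjust([p], len(strata))[0])
                    row.update({"t": t, "p": p, "p_bonferroni": adj})
                else:
                    row["flag"] = "stratum too small for paired test"
            rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: CohortResult, output_dir: Path, make_figures: bool = False) -> None:
    """Write per-record CSV, summaries, run manifest and optional figures."""
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(output_dir / "per_record.csv", index=False)
    result.excluded.to_csv(output_dir / "excluded.csv", index=False)
    result.summary().to_csv(output_dir / "summary.csv", index=False)
    props = result.nonlinear_proportions()
    props.to_csv(output_dir / "nonlinear_proportions.csv", index=False)
    if result.metadata is not None:
        result.summary("prior_mi").to_csv(output_dir / "summary_by_prior_mi.csv", index=False)
    with open(output_dir / "run_manifest.json", "w") as fh:
        json.dump(result.config, fh, indent=2, sort_keys=True)
    if make_figures:
        _figures(result, output_dir)


def _figures(result: CohortResult, output_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    props = result.nonlinear_proportions()
    if not props.empty:
        fig, ax = plt.subplots(figsize=(5, 4))
        xpos = np.arange(len(props))
        ax.bar(xpos, props["percent"],
               yerr=[props["percent"] - props["ci_low"], props["ci_high"] - props["percent"]],
               capsize=4, color="steelblue")
        ax.set_xticks(xpos)
        ax.set_xticklabels(props["statistic"] + "\n" + props["moment"].astype(str))
        ax.set_ylabel("nonlinear series (%)")
        fig.tight_layout()
        fig.savefig(output_dir / "nonlinear_proportions.png", dpi=150)
        plt.close(fig)

    df = result.records.drop_duplicates(subset=["record_id", "moment"])
    wide = df.pivot_table(index="record_id", columns="moment", values=["DET", "LAM"])
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    for ax, stat in zip(axes, ("DET", "LAM")):
        if (stat, "pre") in wide.columns and (stat, "post") in wide.columns:
            sub = wide[stat].dropna()
            for _, r in sub.iterrows():
                ax.plot([0, 1], [r["pre"], r["post"]], "-o", color="grey",
                        alpha=0.4, markersize=3)
            ax.errorbar([0, 1], [sub["pre"].mean(), sub["post"].mean()],
                        yerr=[sub["pre"].std(), sub["post"].std()],
                        fmt="o", color="red", capsize=4, zorder=5)
        ax.set_xticks([0, 1])
        ax.set_xticklabels(["pre", "post"])
        ax.set_title(stat)
    axes[0].set_ylabel("value")
    fig.tight_layout()
    fig.savefig(output_dir / "det_lam_paired.png", dpi=150)
    plt.close(fig)
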