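"""Tabular and graphical reporting of evaluation results.

CSV/JSON tables are the contract surface; plots are optional and
headless-safe (the matplotlib Agg backend is forced).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd

from .evaluate import EvalResults, rank_and_range

__all__ = ["results_table", "write_results_csv", "write_audit_json", "plot_pccc"]


def results_table(results: EvalResults) -> pd.DataFrame:
    """Long-format results with per-stratum coder rank and PCCC range.

    Within each (kind, key) stratum, coders are ranked by PCCC descending
    (ties broken by coder name) and the range column carries max - min PCCC
    across all non-excluded coders, mirroring how figures of this kind are
    annotated.
    """
    df = results.to_frame()
    if df.empty:
        return df
    df["rank"] = pd.NA
    df["range"] = pd.NA
    for (kind, key), sub in df[df["metric"] == "pccc"].groupby(["kind", "key"]):
        cell = [r for r in results.select(kind=kind, key=key)]
        try:
            ordered, rng = rank_and_range(cell)
        except Exception:
            continue
        pos = {coder: i + 1 for i, (coder, _) in enumerate(ordered)}
        mask = (df["kind"] == kind) & (df["key"] == key) & (df["metric"] == "pccc")
        df.loc[mask, "rank"] = df.loc[mask, "coder"].map(pos)
        df.loc[mask, "range"] = rng
    return df


def write_results_csv(results: EvalResults, path) -> pd.DataFrame:
    df = results_table(results)
    df.to_csv(path, index=False, lineterminator="\n")
    return df


def write_audit_json(audit: dict, path, extra: Optional[dict] = None) -> None:
    payload = dict(audit)
    if extra:
        payload.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def plot_pccc(results: EvalResults, path, kind: str = "age_group") -> None:
    """Horizontal bar chart of PCCC by coder for each stratum of ``kind``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results.to_frame()
    df = df[(df["metric"] == "pccc") & (df["kind"] == kind) & ~df["excluded"]]
    keys = sorted(df["key"].unique())
    fig, axes = plt.subplots(
        len(keys), 1, figsize=(7, 2 + 1.5 * len(keys)), squeeze=False
    )
    for ax, key in zip(axes.ravel(), keys):
        sub = df[df["key"] == key].sort_values("point")
        err = [
            (sub["point"] - sub["ci_low"]).clip(lower=0),
            (sub["ci_high"] - sub["point"]).clip(lower=0),
        ]
        ax.barh(sub["coder"], sub["point"], xerr=err, color="#4878a8")
        ax.set_xlim(0, 1)
        ax.set_title(f"{kind}: {key}")
        ax.set_xlabel("PCCC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
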