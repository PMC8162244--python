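"""Result tables, text summary, JSON/TSV output and forest-plot data.

The bundle keeps four blocks — part R2 (with ndf), beta weights, structure
coefficients and inclusive R2 — each as rows of (label, estimate, CI
bounds).  Row order is preserved from the analysis (no sorting by
magnitude), so sign patterns among collinear predictors stay visible.
Plot tables are copied from the bundle, never recomputed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import BootstrapSummary
from .partition import FULL_LABEL, PartitionResult

__all__ = ["ResultBundle", "render_summary", "forestplot_data", "render_forestplot"]

_BLOCKS = ("R2", "BW", "SC", "IR2")


@dataclass
class ResultBundle:
    """Machine-readable results of one variance-partition analysis."""

    R2: pd.DataFrame     # columns: term_set, estimate, ci_lower, ci_upper, ndf
    BW: pd.DataFrame     # columns: predictor, estimate, ci_lower, ci_upper
    SC: pd.DataFrame
    IR2: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def block(self, which: str) -> pd.DataFrame:
        if which not in _BLOCKS:
            raise KeyError(f"unknown block {which!r}; valid keys: {list(_BLOCKS)}")
        return getattr(self, which)

    def to_dict(self) -> dict:
        def frame(df: pd.DataFrame):
            return json.loads(df.to_json(orient="records"))

        return {
            "R2": frame(self.R2),
            "BW": frame(self.BW),
            "SC": frame(self.SC),
            "IR2": frame(self.IR2),
            "metadata": self.metadata,
            "warnings": self.warnings,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "ResultBundle":
        if "\n" not in text_or_path and text_or_path.endswith(".json"):
            with open(text_or_path) as fh:
                doc = json.load(fh)
        else:
            doc = json.loads(text_or_path)
        frames = {}
        for key in _BLOCKS:
            df = pd.DataFrame(doc[key])
            frames[key] = df
        return cls(
            R2=frames["R2"],
            BW=frames["BW"],
            SC=frames["SC"],
            IR2=frames["IR2"],
            metadata=doc.get("metadata", {}),
            warnings=doc.get("warnings", []),
        )

    def to_tsv(self, prefix: str) -> list[str]:
        paths = []
        for key in _BLOCKS:
            path = f"{prefix}.{key}.tsv"
            self.block(key).to_csv(path, sep="\t", index=False)
            paths.append(path)
        return paths


def build_bundle(
    part: PartitionResult,
    boot: dict[str, BootstrapSummary],
    effect_cols: list[str],
    metadata: dict,
) -> ResultBundle:
    """Assemble a ResultBundle from partition, bootstrap and effect results."""

    def ci(name):
        s = boot.get(name)
        if s is None:
            return (np.nan, np.nan)
        return (s.ci_lower, s.ci_upper)

    r2_rows = [
        {
            "term_set": FULL_LABEL,
            "estimate": part.full_r2,
            "ci_lower": ci(f"R2:{FULL_LABEL}")[0],
            "ci_upper": ci(f"R2:{FULL_LABEL}")[1],
            "ndf": _full_ndf(metadata),
        }
    ]
    for row in part.rows:
        lo, hi = ci(f"R2:{row.label}")
        r2_rows.append(
            {
                "term_set": row.label,
                "estimate": row.part_r2,
                "ci_lower": lo,
                "ci_upper": hi,
                "ndf": row.ndf,
            }
        )

    def effect_frame(block: str) -> pd.DataFrame:
        recs = []
        for col in effect_cols:
            s = boot.get(f"{block}:{col}")
            recs.append(
                {
                    "predictor": col,
                    "estimate": s.estimate if s else np.nan,
                    "ci_lower": s.ci_lower if s else np.nan,
                    "ci_upper": s.ci_upper if s else np.nan,
                }
            )
        return pd.DataFrame(recs, columns=["predictor", "estimate", "ci_lower", "ci_upper"])

    return ResultBundle(
        R2=pd.DataFrame(r2_rows, columns=["term_set", "estimate", "ci_lower", "ci_upper", "ndf"]),
        BW=effect_frame("BW"),
        SC=effect_frame("SC"),
        IR2=effect_frame("IR2"),
        metadata=metadata,
        warnings=sorted({w for s in boot.values() for w in s.warnings} | set(part.warnings)),
    )


def _full_ndf(metadata: dict) -> int:
    return int(metadata.get("ndf_full", 0))


def _fmt(x, round_to: int) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.{round_to}f}"


def _render_block(df: pd.DataFrame, label_col: str, round_to: int, extra: list[str] = ()) -> list[str]:
    header = [label_col, "estimate", "CI_lower", "CI_upper", *extra]
    rows = [header]
    for _, r in df.iterrows():
        row = [
            str(r[label_col]),
            _fmt(r["estimate"], round_to),
            _fmt(r["ci_lower"], round_to),
            _fmt(r["ci_upper"], round_to),
        ]
        for e in extra:
            row.append("NA" if pd.isna(r[e]) else str(int(r[e])))
        rows.append(row)
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    return ["  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip() for r in rows]


def render_summary(bundle: ResultBundle, round_to: int = 4) -> str:
    """Plain-text summary: full and part R2 (with ndf), then BW, SC, IR2.

    The bootstrap-warning count is appended at the bottom.
    """
    md = bundle.metadata
    lines = [
        "Variance partitioning of a mixed model "
        f"({md.get('family', '?')}, {md.get('link', '?')} link)",
        f"nboot = {md.get('nboot', 0)}, CI level = {md.get('ci_level', 0.95)}, "
        f"seed = {md.get('seed')}",
        "",
        "Part R2 (variance uniquely explained; denominator from the full model):",
    ]
    lines += _render_block(bundle.R2, "term_set", round_to, extra=["ndf"])
    lines += ["", "Beta weights (standardized slopes):"]
    lines += _render_block(bundle.BW, "predictor", round_to)
    lines += ["", "Structure coefficients cor(eta, x):"]
    lines += _render_block(bundle.SC, "predictor", round_to)
    lines += ["", "Inclusive R2 (SC^2 x R2):"]
    lines += _render_block(bundle.IR2, "predictor", round_to)
    n_warn = len(bundle.warnings)
    lines += ["", f"Warnings during fitting/bootstrapping: {n_warn}"]
    return "\n".join(lines)


def forestplot_data(bundle: ResultBundle, which: str = "R2") -> pd.DataFrame:
    """Rows (label, estimate, lower, upper) for a forest plot, bundle order."""
    df = bundle.block(which)
    label_col = "term_set" if which == "R2" else "predictor"
    out = pd.DataFrame(
        {
            "label": df[label_col],
            "estimate": df["estimate"],
            "lower": df["ci_lower"],
            "upper": df["ci_upper"],
        }
    )
    if which == "SC":
        vals = out["estimate"].dropna()
        if ((vals < -1) | (vals > 1)).any():
            raise ValueError("structure coefficients outside [-1, 1]")
    return out


def render_forestplot(table: pd.DataFrame, path=None, ax=None, title: str | None = None):
    """Draw a horizontal point+interval plot from a forestplot_data table."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 0.5 * len(table) + 1.5))
    else:
        fig = ax.figure
    ypos = np.arange(len(table))[::-1]
    est = table["estimate"].to_numpy(dtype=float)
    lo = table["lower"].to_numpy(dtype=float)
    hi = table["upper"].to_numpy(dtype=float)
    has_ci = np.isfinite(lo) & np.isfinite(hi)
    ax.errorbar(
        est[has_ci],
        ypos[has_ci],
        xerr=[est[has_ci] - lo[has_ci], hi[has_ci] - est[has_ci]],
        fmt="o",
        color="black",
        capsize=3,
    )
    ax.plot(est[~has_ci], ypos[~has_ci], "o", color="black")
    ax.set_yticks(ypos)
    ax.set_yticklabels(table["label"])
    ax.axvline(0.0, color="grey", lw=0.8, ls=":")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return ax
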