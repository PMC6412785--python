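"""Group summaries, Tukey all-pairs comparisons, and report assembly.

Contact angles across three or more dish types are compared with the
Tukey HSD procedure (studentized-range distribution, equal-variance
pooling); morphometric mono-vs-multi contrasts use the unpaired t-test
in :mod:`multinuc.morphometry`.  Reports are tidy CSV tables plus
convenience plots; the CSVs are the contract and are written
deterministically (fixed float format, sorted keys) so identical inputs
give byte-identical files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1 or self.sd < 0:
            raise ValueError("need n >= 1 and sd >= 0")


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    statistic: float   # difference of means (a − b)
    p: float
    significant: bool


def summarize_groups(samples: Mapping[str, Sequence[float]]) -> list[GroupSummary]:
    """Mean ± SD (n−1 denominator) per labeled sample."""
    out = []
    for label in sorted(samples):
        x = np.asarray(samples[label], float)
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        out.append(GroupSummary(label=str(label), n=int(x.size),
                                mean=float(x.mean()), sd=sd))
    return out


def tukey_all_pairs(samples: Mapping[str, Sequence[float]],
                    alpha: float = 0.05) -> list[ComparisonResult]:
    """Tukey HSD over all pairs of ≥3 groups.

    Results are returned in sorted-label pair order and are invariant to
    the order the groups are supplied in.
    """
    labels = sorted(samples)
    if len(labels) < 3:
        raise ValueError("Tukey HSD needs >= 3 groups; use an unpaired t-test "
                         "for two groups")
    arrays = [np.asarray(samples[k], float) for k in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    res = stats.tukey_hsd(*arrays)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = float(res.pvalue[i, j])
            out.append(ComparisonResult(
                group_a=labels[i], group_b=labels[j],
                statistic=float(arrays[i].mean() - arrays[j].mean()),
                p=p, significant=bool(p < alpha),
            ))
    return out


def comparisons_frame(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in comparisons])


def write_csv(df: pd.DataFrame, path: Path | str) -> Path:
    """Deterministic CSV write (fixed float format, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def build_report(out_dir: Path | str,
                 tables: Mapping[str, pd.DataFrame],
                 comparisons: Sequence[ComparisonResult] = (),
                 plots: bool = True) -> list[Path]:
    """Write report CSVs (and convenience plots) into ``out_dir``.

    ``tables`` maps a base name to a tidy DataFrame; each becomes
    ``<name>.csv``.  Recognized names get a companion PNG plot:
    ``r_multi_timecourse`` (R_multi vs time per condition),
    ``nuclei_histogram`` (nuclei-per-cell bars), and
    ``morphometry_groups`` (group means ± SD bars with significance
    marks from ``comparisons``).  Plots are conveniences; the CSVs are
    the contract.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in sorted(tables.items()):
        if df is None:
            raise FileNotFoundError(f"report table {name!r} is missing")
        written.append(write_csv(df, out_dir / f"{name}.csv"))
    if comparisons:
        written.append(write_csv(comparisons_frame(comparisons),
                                 out_dir / "comparisons.csv"))
    if plots:
        written.extend(_make_plots(out_dir, tables, comparisons))
    return written


def _make_plots(out_dir: Path, tables: Mapping[str, pd.DataFrame],
                comparisons: Sequence[ComparisonResult]) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if "r_multi_timecourse" in tables:
        df = tables["r_multi_timecourse"]
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for label, sub in df.groupby("condition"):
            ax.plot(sub["timepoint_h"], sub["r_multi"], "o-", label=label)
        ax.set_xlabel("time after seeding (h)")
        ax.set_ylabel("multinucleated cells R_multi (%)")
        ax.set_ylim(0, 100)
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = out_dir / "r_multi_timecourse.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    if "nuclei_histogram" in tables:
        df = tables["nuclei_histogram"]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(df["n_nuclei"], df["n_cells"], color="steelblue")
        ax.set_xlabel("nuclei per cell")
        ax.set_ylabel("cells")
        fig.tight_layout()
        p = out_dir / "nuclei_histogram.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    if "morphometry_groups" in tables:
        df = tables["morphometry_groups"]
        sig = {c.group_a + "|" + c.group_b: c.significant for c in comparisons}
        metrics = df["metric"].unique()
        fig, axes = plt.subplots(1, len(metrics), figsize=(2.2 * len(metrics), 3))
        axes = np.atleast_1d(axes)
        for ax, m in zip(axes, metrics):
            sub = df[df["metric"] == m]
            ax.bar(sub["group"], sub["mean"], yerr=sub["sd"], capsize=3,
                   color=["#888", "#c33"])
            star = any(v for k, v in sig.items() if m in k) or \
                bool(sub.get("significant", pd.Series(dtype=bool)).any())
            ax.set_title(("*" if star else "") + m, fontsize=8)
        fig.tight_layout()
        p = out_dir / "morphometry_groups.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
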