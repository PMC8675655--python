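"""Ribosomal subunit stoichiometry summaries from proteomics tables.

A heterozygous ribosomal-protein mutation removes one copy of a single
small-subunit (SSU) or large-subunit (LSU) protein gene, and the resulting
imbalance between the two subunit classes is read out from per-protein log2
fold changes measured by quantitative mass spectrometry.  This module
classifies cytoplasmic ribosomal proteins by gene symbol and summarizes the
class-level imbalance: per-class mean log fold change with a Student-t 95%
confidence interval and a one-sample Wilcoxon test against zero, plus a
Mann–Whitney comparison of the SSU and LSU distributions.

The table is expected to carry one log fold change per protein per named
comparison (replicates averaged upstream).  Raw spectra processing is out
of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import TestResult, mann_whitney_u, mean_ci, one_sample_wilcoxon

_SSU_RE = re.compile(r"^rps(\d+[a-z]*|a)$", re.IGNORECASE)
_LSU_RE = re.compile(r"^rpl\w*$", re.IGNORECASE)
_MITO_RE = re.compile(r"^mrp[sl]", re.IGNORECASE)


def classify_ribosomal(gene_symbol: str) -> str:
    """Classify a gene symbol as cytoplasmic SSU, LSU, or other.

    ``RpS*`` and ``RpSA`` → ``"SSU"``; ``RpL*`` (including the P-stalk
    ``RpLP*``) → ``"LSU"``; mitochondrial ``mRpS*``/``mRpL*`` and anything
    else → ``"other"``.  Case-insensitive.
    """
    if not gene_symbol:
        raise ValueError("empty gene symbol")
    s = gene_symbol.strip()
    if _MITO_RE.match(s):
        return "other"
    if _SSU_RE.match(s):
        return "SSU"
    if _LSU_RE.match(s):
        return "LSU"
    return "other"


@dataclass
class ClassSummary:
    n: int
    mean_lfc: float
    ci95: tuple[float, float]
    p_vs_zero: float
    test_vs_zero: TestResult | None = None


@dataclass
class ImbalanceSummary:
    """Per-class imbalance summary for one comparison."""

    comparison: str
    classes: dict[str, ClassSummary] = field(default_factory=dict)
    p_ssu_vs_lsu: float = float("nan")
    test_ssu_vs_lsu: TestResult | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": self.comparison,
                "subunit_class": cls,
                "n": cs.n,
                "mean_lfc": cs.mean_lfc,
                "ci95_low": cs.ci95[0],
                "ci95_high": cs.ci95[1],
                "p_vs_zero": cs.p_vs_zero,
                "p_ssu_vs_lsu": self.p_ssu_vs_lsu,
            }
            for cls, cs in self.classes.items()
        ]
        return pd.DataFrame(rows)


def load_protein_table(path, comparison_cols: list[str] | None = None) -> pd.DataFrame:
    """Read a protein log-fold-change CSV into long format.

    Accepts either long format (``gene_symbol, comparison, lfc``) or wide
    format with one column per comparison (``comparison_cols``).  Subunit
    classes are (re)derived from gene symbols.
    """
    df = pd.read_csv(path)
    if comparison_cols:
        id_cols = [c for c in ("protein_id", "gene_symbol") if c in df.columns]
        df = df.melt(id_vars=id_cols, value_vars=comparison_cols,
                     var_name="comparison", value_name="lfc")
    if "gene_symbol" not in df.columns or "lfc" not in df.columns:
        raise ValueError("protein table needs gene_symbol and lfc columns")
    df = df.copy()
    df["subunit_class"] = df["gene_symbol"].map(classify_ribosomal)
    if not np.isfinite(df["lfc"]).all():
        raise ValueError("log fold changes must be finite")
    return df


def summarize_imbalance(table: pd.DataFrame, comparison: str | None = None) -> ImbalanceSummary:
    """Summarize SSU/LSU imbalance for one comparison.

    Per class: n, mean log2 fold change, Student-t 95% CI, two-sided
    one-sample Wilcoxon signed-rank against zero.  Across classes: two-sided
    Mann–Whitney U on the SSU vs LSU values.  Degenerate all-zero classes
    get p = NaN (the signed-rank test is undefined when every value is at
    the null).
    """
    df = table
    if "subunit_class" not in df.columns:
        df = df.assign(subunit_class=df["gene_symbol"].map(classify_ribosomal))
    if comparison is not None:
        if "comparison" in df.columns:
            df = df[df["comparison"] == comparison]
        name = comparison
    else:
        name = str(df["comparison"].iloc[0]) if "comparison" in df.columns else ""

    out = ImbalanceSummary(comparison=name)
    values: dict[str, np.ndarray] = {}
    for cls in ("SSU", "LSU"):
        v = df.loc[df["subunit_class"] == cls, "lfc"].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"class {cls} has {len(v)} proteins; need >= 2")
        values[cls] = v
        try:
            t = one_sample_wilcoxon(v, mu0=0.0, two_sided=True)
            p, tres = t.p_value, t
        except ValueError:  # all values exactly zero
            p, tres = float("nan"), None
        out.classes[cls] = ClassSummary(
            n=len(v),
            mean_lfc=float(v.mean()),
            ci95=mean_ci(v, 0.95),
            p_vs_zero=p,
            test_vs_zero=tres,
        )
    try:
        mw = mann_whitney_u(values["SSU"], values["LSU"], two_sided=True)
        out.p_ssu_vs_lsu = mw.p_value
        out.test_ssu_vs_lsu = mw
    except ValueError:  # fully degenerate pooled values
        out.p_ssu_vs_lsu = float("nan")
    return out
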