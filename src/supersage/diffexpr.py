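"""Differential-expression statistics for SuperSAGE tag counts.

Two test families act together on tag proportions:

* a pairwise two-proportion Z-test between libraries (the classical SAGE
  test of Kal et al.): z = (p1 - p2) / sqrt(p0 (1 - p0) (1/n1 + 1/n2))
  with p0 the pooled proportion, two-sided against the standard normal;
* a replicated goodness-of-fit G-test over a subset of libraries, whose
  likelihood-ratio statistic decomposes exactly as
  G_total = G_pooled + G_heterogeneity, where G_pooled measures the
  between-group difference after pooling replicate libraries and
  G_heterogeneity measures within-group inconsistency.

Zero counts are replaced by a small "zero-substitution value" (0.345 by
default) before expected-frequency and ratio computation, so that tags
absent from one condition are kept in the analysis rather than dropped.
Fold change is the raw count ratio after zero substitution, reported as
the nearest integer of max(R, 1/R); no library-size normalisation is
applied to the ratio.

Differentially expressed tags are sorted into four classes by a
conjunction of test outcomes over the five-library design (control and
LowCa at 2 h and 12 h, HighCa at 12 h only):

1. control vs LowCa regardless of time,
2. LowCa effect at one time point only (time-dependent),
3. control vs HighCa at 12 h,
4. global effect of altered water calcium at 12 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_away
from .matrix import TagCountMatrix

#: Default zero-substitution constant for zero tag counts.
ZERO_SUB = 0.345

#: The five library roles of the two-time-point, two-challenge design.
ROLES = ("C2h", "LowCa2h", "C12h", "HighCa12h", "LowCa12h")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ZTestResult:
    z: float
    p: float
    c1: int
    n1: int
    c2: int
    n2: int


@dataclass
class GTestResult:
    """Replicated G-test decomposition with the per-class decision flags."""

    G_total: float
    G_pooled: float
    G_heterogeneity: float
    df_total: int
    df_pooled: int
    df_heterogeneity: int
    p_total: float
    p_pooled: float
    p_heterogeneity: float
    #: every rule passes: overall and pooled G significant, groups homogeneous
    pass_all_rules: bool
    #: the intrinsic (overall) G is significant
    pass_intrinsic: bool
    #: the heterogeneity component is significant (groups inconsistent)
    fail_homogeneity: bool


@dataclass
class ExpressionRatio:
    control_count: int
    treatment_count: int
    zero_sub: float
    R: float
    direction: str  # "up" | "down"
    fold: int


@dataclass
class ComparisonDesign:
    """A named G-test over groups of library roles."""

    name: str
    groups: dict[str, list[str]]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for libs in self.groups.values():
            for lib in libs:
                if lib in seen:
                    raise ValueError(f"library {lib!r} in more than one group")
                seen.add(lib)


def standard_designs(alpha: float = 0.05) -> dict[str, ComparisonDesign]:
    """The four G-test designs over the five-library role set."""
    return {
        "G-Test1": ComparisonDesign(
            "G-Test1",
            {"Control": ["C2h", "C12h"], "LowCa": ["LowCa2h", "LowCa12h"]},
            alpha,
        ),
        "G-Test2": ComparisonDesign(
            "G-Test2",
            {"2h": ["C2h", "LowCa2h"], "12h": ["C12h", "LowCa12h"]},
            alpha,
        ),
        "G-Test3": ComparisonDesign(
            "G-Test3",
            {"C": ["C12h"], "LowCa": ["LowCa12h"], "HighCa": ["HighCa12h"]},
            alpha,
        ),
        "G-Test4": ComparisonDesign(
            "G-Test4",
            {"C": ["C12h"], "Altered": ["LowCa12h", "HighCa12h"]},
            alpha,
        ),
    }


@dataclass
class DifferentialExpressionRecord:
    tag: str
    counts: dict[str, int]
    g_results: dict[str, GTestResult]
    z_results: dict[str, ZTestResult]
    ratios: dict[str, ExpressionRatio]
    de_class: set[int] = field(default_factory=set)
    retained: bool = False

    @property
    def max_fold(self) -> int:
        return max((r.fold for r in self.ratios.values()), default=0)


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def z_test(c1: int, n1: int, c2: int, n2: int) -> ZTestResult:
    """Two-proportion Z-test of one tag's frequency between two libraries.

    Degenerate case: when both counts are zero (pooled proportion 0) the
    test is defined as z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if not (0 <= c1 <= n1 and 0 <= c2 <= n2):
        raise ValueError("counts must lie in [0, total]")
    z, p = _z_arrays(
        np.array([c1], float), float(n1), np.array([c2], float), float(n2)
    )
    return ZTestResult(float(z[0]), float(p[0]), c1, n1, c2, n2)


def _z_arrays(c1: np.ndarray, n1: float, c2: np.ndarray, n2: float):
    """Vectorised two-sided two-proportion z over arrays of counts."""
    p0 = (c1 + c2) / (n1 + n2)
    var = p0 * (1.0 - p0) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (c1 / n1 - c2 / n2) / np.sqrt(var), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, np.minimum(p, 1.0)


def _g_of_table(obs: np.ndarray) -> np.ndarray:
    """Likelihood-ratio G of 2 x L tables, vectorised over the first axis.

    ``obs`` has shape (T, 2, L) with nonnegative (possibly non-integer,
    after zero substitution) entries.  G = 2 sum O ln(O / E) with E the
    usual independence expectation; empty cells contribute zero.
    """
    row = obs.sum(axis=2, keepdims=True)
    col = obs.sum(axis=1, keepdims=True)
    n = obs.sum(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = row * col / n
        term = np.where(obs > 0, obs * np.log(obs / e), 0.0)
    return 2.0 * term.sum(axis=(1, 2))


def _g_decompose(
    counts: np.ndarray,
    totals: np.ndarray,
    group_cols: Sequence[Sequence[int]],
    zero_sub: float = ZERO_SUB,
):
    """Replicated G decomposition, vectorised over tags.

    ``counts``: (T, L) tag counts for the L libraries of the design;
    ``totals``: (L,) library totals; ``group_cols``: column indices of
    each group.  Zero tag counts are replaced by ``zero_sub`` before any
    expected-frequency computation, consistently in all three components,
    which preserves the exact additivity G_total = G_pooled + G_het.
    """
    counts = np.atleast_2d(np.asarray(counts, float))
    adj = np.where(counts > 0, counts, zero_sub)
    other = np.maximum(totals[None, :] - counts, zero_sub)
    full = np.stack([adj, other], axis=1)  # (T, 2, L)

    g_total = _g_of_table(full)
    pooled = np.stack(
        [full[:, :, cols].sum(axis=2) for cols in group_cols], axis=2
    )  # (T, 2, n_groups)
    g_pooled = _g_of_table(pooled)
    g_het = np.zeros_like(g_total)
    for cols in group_cols:
        if len(cols) > 1:
            g_het += _g_of_table(full[:, :, cols])

    L = counts.shape[1]
    g = len(group_cols)
    return g_total, g_pooled, g_het, L - 1, g - 1, L - g


def g_test(
    counts: Mapping[str, int] | Sequence[int],
    totals: Mapping[str, int] | Sequence[int],
    design: ComparisonDesign,
    zero_sub: float = ZERO_SUB,
) -> GTestResult:
    """Replicated G-test of one tag over the libraries of ``design``.

    ``counts`` and ``totals`` map library names to the tag count and the
    library total (sequences are accepted when the design's libraries are
    positional).  Returns the full decomposition with decision flags at
    the design's alpha.
    """
    libs = [lib for libs in design.groups.values() for lib in libs]
    if isinstance(counts, Mapping):
        missing = [lib for lib in libs if lib not in counts]
        if missing:
            raise KeyError(f"design references absent libraries: {missing}")
        c = np.array([counts[lib] for lib in libs], float)
        n = np.array([totals[lib] for lib in libs], float)
    else:
        c = np.asarray(counts, float)
        n = np.asarray(totals, float)
        if len(c) != len(libs):
            raise ValueError("count vector does not match design libraries")
    if (n <= 0).any():
        raise ValueError("library totals must be positive")

    idx = 0
    group_cols = []
    for g_libs in design.groups.values():
        group_cols.append(list(range(idx, idx + len(g_libs))))
        idx += len(g_libs)

    gt, gp, gh, dft, dfp, dfh = _g_decompose(c[None, :], n, group_cols, zero_sub)
    return _make_g_result(
        float(gt[0]), float(gp[0]), float(gh[0]), dft, dfp, dfh, design.alpha
    )


def _chi2_sf(g: np.ndarray, df: int) -> np.ndarray:
    if df <= 0:
        return np.ones_like(np.asarray(g, float))
    return stats.chi2.sf(np.maximum(g, 0.0), df)


def _make_g_result(gt, gp, gh, dft, dfp, dfh, alpha) -> GTestResult:
    pt = float(_chi2_sf(np.array([gt]), dft)[0])
    pp = float(_chi2_sf(np.array([gp]), dfp)[0])
    ph = float(_chi2_sf(np.array([gh]), dfh)[0])
    return GTestResult(
        G_total=gt,
        G_pooled=gp,
        G_heterogeneity=gh,
        df_total=dft,
        df_pooled=dfp,
        df_heterogeneity=dfh,
        p_total=pt,
        p_pooled=pp,
        p_heterogeneity=ph,
        pass_all_rules=(pt < alpha) and (pp < alpha) and (ph >= alpha),
        pass_intrinsic=pt < alpha,
        fail_homogeneity=ph < alpha,
    )


def fold_change(
    control_count: int, treatment_count: int, zero_sub: float = ZERO_SUB
) -> ExpressionRatio:
    """Zero-substitution expression ratio and reported fold.

    R = treatment' / control' where a zero count is first replaced by the
    zero-substitution constant; the reported fold is the nearest integer
    (half away from zero) of max(R, 1/R), with the direction "up" when
    R >= 1 and "down" otherwise.
    """
    if control_count < 0 or treatment_count < 0:
        raise ValueError("counts must be nonnegative")
    c = control_count if control_count > 0 else zero_sub
    t = treatment_count if treatment_count > 0 else zero_sub
    r = t / c
    fold = int(round_half_away(max(r, 1.0 / r)))
    return ExpressionRatio(
        control_count=control_count,
        treatment_count=treatment_count,
        zero_sub=zero_sub,
        R=r,
        direction="up" if r >= 1.0 else "down",
        fold=fold,
    )


# ---------------------------------------------------------------------------
# four-class classifier
# ---------------------------------------------------------------------------

def classify_tags(
    matrix: TagCountMatrix,
    role_map: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    min_fold: int = 2,
    zero_sub: float = ZERO_SUB,
) -> list[DifferentialExpressionRecord]:
    """Classify every tag of the matrix into the four DE classes.

    ``role_map`` maps the five library roles (C2h, LowCa2h, C12h,
    HighCa12h, LowCa12h) to the matrix's column names; by default the
    columns are expected to be named by role.  A tag is ``retained`` when
    it falls in at least one class and at least one of its per-challenge
    expression ratios reaches ``min_fold``.
    """
    role_map = dict(role_map) if role_map else {r: r for r in ROLES}
    missing = [r for r in ROLES if role_map.get(r) not in matrix.counts.columns]
    if missing:
        raise KeyError(f"role mapping incomplete, missing roles: {missing}")

    cols = [role_map[r] for r in ROLES]
    C = matrix.counts[cols].to_numpy(dtype=float)  # (T, 5) ordered by ROLES
    N = matrix.totals[cols].to_numpy(dtype=float)
    i = {r: k for k, r in enumerate(ROLES)}
    designs = standard_designs(alpha)

    # G decompositions, vectorised over all tags at once
    def run(design_name, role_lists):
        libs = [r for rs in role_lists for r in rs]
        col_idx = [i[r] for r in libs]
        groups, at = [], 0
        for rs in role_lists:
            groups.append(list(range(at, at + len(rs))))
            at += len(rs)
        gt, gp, gh, dft, dfp, dfh = _g_decompose(
            C[:, col_idx], N[col_idx], groups, zero_sub
        )
        return {
            "gt": gt, "gp": gp, "gh": gh,
            "pt": _chi2_sf(gt, dft), "pp": _chi2_sf(gp, dfp),
            "ph": _chi2_sf(gh, dfh), "df": (dft, dfp, dfh),
        }

    g1 = run("G-Test1", [["C2h", "C12h"], ["LowCa2h", "LowCa12h"]])
    g2 = run("G-Test2", [["C2h", "LowCa2h"], ["C12h", "LowCa12h"]])
    g3 = run("G-Test3", [["C12h"], ["LowCa12h"], ["HighCa12h"]])
    g4 = run("G-Test4", [["C12h"], ["LowCa12h", "HighCa12h"]])

    # pairwise Z-tests
    z_cl, p_cl = _z_arrays(
        C[:, i["C2h"]] + C[:, i["C12h"]], N[i["C2h"]] + N[i["C12h"]],
        C[:, i["LowCa2h"]] + C[:, i["LowCa12h"]], N[i["LowCa2h"]] + N[i["LowCa12h"]],
    )
    z_cl2, p_cl2 = _z_arrays(C[:, i["C2h"]], N[i["C2h"]], C[:, i["LowCa2h"]], N[i["LowCa2h"]])
    z_cl12, p_cl12 = _z_arrays(C[:, i["C12h"]], N[i["C12h"]], C[:, i["LowCa12h"]], N[i["LowCa12h"]])
    z_ch12, p_ch12 = _z_arrays(C[:, i["C12h"]], N[i["C12h"]], C[:, i["HighCa12h"]], N[i["HighCa12h"]])

    def pass_all(g):
        return (g["pt"] < alpha) & (g["pp"] < alpha) & (g["ph"] >= alpha)

    cls1 = pass_all(g1) & (p_cl < alpha)
    cls2 = (
        (g1["pt"] < alpha)
        & (g2["pt"] < alpha)
        & ~pass_all(g1)
        & (g2["ph"] < alpha)
        & ((p_cl2 < alpha) | (p_cl12 < alpha))
    )
    cls3 = pass_all(g3) & (p_ch12 < alpha)
    cls4 = pass_all(g4) & ((p_cl12 < alpha) | (p_ch12 < alpha))

    records: list[DifferentialExpressionRecord] = []
    tags = list(matrix.tags)
    Ci = matrix.counts[cols].to_numpy(dtype=np.int64)
    design_runs = {"G-Test1": g1, "G-Test2": g2, "G-Test3": g3, "G-Test4": g4}
    z_runs = {
        "C_vs_LowCa": (z_cl, p_cl,
                       Ci[:, i["C2h"]] + Ci[:, i["C12h"]], int(N[i["C2h"]] + N[i["C12h"]]),
                       Ci[:, i["LowCa2h"]] + Ci[:, i["LowCa12h"]], int(N[i["LowCa2h"]] + N[i["LowCa12h"]])),
        "C2h_vs_LowCa2h": (z_cl2, p_cl2, Ci[:, i["C2h"]], int(N[i["C2h"]]),
                           Ci[:, i["LowCa2h"]], int(N[i["LowCa2h"]])),
        "C12h_vs_LowCa12h": (z_cl12, p_cl12, Ci[:, i["C12h"]], int(N[i["C12h"]]),
                             Ci[:, i["LowCa12h"]], int(N[i["LowCa12h"]])),
        "C12h_vs_HighCa12h": (z_ch12, p_ch12, Ci[:, i["C12h"]], int(N[i["C12h"]]),
                              Ci[:, i["HighCa12h"]], int(N[i["HighCa12h"]])),
    }
    ratio_pairs = {
        "LowCa_2h": ("C2h", "LowCa2h"),
        "LowCa_12h": ("C12h", "LowCa12h"),
        "HighCa_12h": ("C12h", "HighCa12h"),
    }

    for t in range(len(tags)):
        classes = set()
        if cls1[t]:
            classes.add(1)
        if cls2[t]:
            classes.add(2)
        if cls3[t]:
            classes.add(3)
        if cls4[t]:
            classes.add(4)
        ratios = {
            name: fold_change(int(Ci[t, i[c]]), int(Ci[t, i[tr]]), zero_sub)
            for name, (c, tr) in ratio_pairs.items()
        }
        g_results = {
            name: _make_g_result(
                float(g["gt"][t]), float(g["gp"][t]), float(g["gh"][t]),
                *g["df"], alpha,
            )
            for name, g in design_runs.items()
        }
        z_results = {
            name: ZTestResult(float(z[t]), float(p[t]), int(c1[t]), n1, int(c2[t]), n2)
            for name, (z, p, c1, n1, c2, n2) in z_runs.items()
        }
        max_fold = max(r.fold for r in ratios.values())
        records.append(
            DifferentialExpressionRecord(
                tag=tags[t],
                counts={r: int(Ci[t, i[r]]) for r in ROLES},
                g_results=g_results,
                z_results=z_results,
                ratios=ratios,
                de_class=classes,
                retained=bool(classes) and max_fold >= min_fold,
            )
        )
    return records


def records_to_frame(records: Iterable[DifferentialExpressionRecord]) -> pd.DataFrame:
    """Flatten DE records into a TSV-friendly DataFrame."""
    rows = []
    for r in records:
        row: dict = {"tag": r.tag}
        row.update({f"count_{k}": v for k, v in r.counts.items()})
        for name, g in r.g_results.items():
            key = name.replace("-", "_")
            row[f"{key}_G"] = g.G_total
            row[f"{key}_p"] = g.p_total
            row[f"{key}_p_het"] = g.p_heterogeneity
        for name, z in r.z_results.items():
            row[f"z_{name}"] = z.z
            row[f"p_{name}"] = z.p
        for name, ratio in r.ratios.items():
            row[f"fold_{name}"] = ratio.fold
            row[f"dir_{name}"] = ratio.direction
        row["classes"] = ",".join(str(c) for c in sorted(r.de_class))
        row["retained"] = r.retained
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-level aggregation and platform concordance
# ---------------------------------------------------------------------------

def gene_level_expression(
    matrix: TagCountMatrix, tag_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Sum tag counts per annotated gene, per library.

    Tags without a gene assignment are skipped.  Mirrors the cumulative
    SuperSAGE signal used when comparing against per-gene qPCR.
    """
    genes = matrix.counts.index.map(lambda t: tag_to_gene.get(t))
    keep = genes.notna()
    if not keep.any():
        return pd.DataFrame(columns=matrix.libraries)
    sub = matrix.counts[keep].copy()
    sub.index = genes[keep]
    return sub.groupby(level=0).sum()


def concordance_correlation(
    sage_log2_folds: Sequence[float], qpcr_log2_folds: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between log2 fold changes of the two platforms."""
    x = np.asarray(sage_log2_folds, float)
    y = np.asarray(qpcr_log2_folds, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-d vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("fold changes must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
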