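"""Gene-level enrichment statistics for pooled CRISPR screens.

The scoring procedure operates on per-guide read counts from experimental
(selected) and control (unselected) libraries:

1. assemble a guides x libraries count matrix keyed by gene; guides with no
   observed reads in a library are missing,
2. set missing values to one, then replace every count equal to one by the
   per-gene median of that gene's guide counts — separately per library
   (median imputation; a single pass with pre-replacement medians),
3. total normalization: divide each count by its library's post-imputation
   sum, giving per-guide frequencies,
4. per gene, form the log2-ratios of paired experimental/control guide
   frequencies (one ratio per guide per replicate pair),
5. compute the mean m, sample standard deviation s and t-score
   t = m / (s / sqrt(n)) of the ratios, and refer t to the standard normal
   distribution for a p-value (a z-test approximation to the paired
   t-test),
6. adjust p-values by Benjamini-Hochberg and Bonferroni.

Referencing the statistic to the normal rather than Student's t makes the
test slightly anti-conservative for small guide numbers; with n = 5 guides
the true one-sided type-I error at nominal alpha = 0.05 is
P(T_4 > z_0.95) ~ 0.086.  This is a property of the method, documented in
docs/methods.md, not a defect of the implementation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from guidescreen.guide_report import GuideCounts, GuideReference

TAILS = ("enrichment", "depletion", "two_sided")


@dataclass
class CountMatrix:
    """Genes x libraries count structure holding original, imputed and
    normalized per-guide counts.

    ``original`` holds integer counts with 0 marking a guide never observed
    in that library (a missing value).  ``imputed`` (all values >= 1) and
    ``normalized`` (columns summing to 1) are filled by :func:`impute` and
    :func:`normalize`.  Experimental library j is paired with control
    library j by declared order.
    """

    genes: pd.Series            # index: guide sequence -> gene identifier
    original: pd.DataFrame      # index: guide sequence; columns: library labels
    exp_labels: list[str]
    ctrl_labels: list[str]
    imputed: pd.DataFrame | None = None
    normalized: pd.DataFrame | None = None

    @property
    def guide_list(self) -> list[str]:
        return self.original.index.tolist()

    @property
    def gene_list(self) -> list[str]:
        seen = dict.fromkeys(self.genes)
        return list(seen)

    def guides_of(self, gene: str) -> list[str]:
        return self.genes.index[self.genes == gene].tolist()


def assemble_matrix(
    experimental: Sequence[GuideCounts],
    control: Sequence[GuideCounts],
    reference: GuideReference,
    by: str = "gene",
) -> CountMatrix:
    """Build the count matrix from per-library guide counts.

    Requires at least one experimental and one control library, all counted
    against the same reference.  Every reference guide appears exactly once
    per library; a zero count records the guide as missing in that library.
    """
    if not experimental or not control:
        raise ValueError("need at least one experimental and one control library")
    if len(experimental) != len(control):
        raise ValueError(
            "experimental and control libraries must come in pairs "
            f"(got {len(experimental)} vs {len(control)})"
        )
    guides = reference.guides
    for lib in (*experimental, *control):
        if set(lib.counts) != set(guides):
            raise ValueError(
                f"library {lib.library_label!r} was not counted against the same reference"
            )
    exp_labels = [lib.library_label or f"exp_{i + 1}" for i, lib in enumerate(experimental)]
    ctrl_labels = [lib.library_label or f"ctrl_{i + 1}" for i, lib in enumerate(control)]
    if set(exp_labels) & set(ctrl_labels):
        raise ValueError("experimental and control library labels must be distinct")
    data = {
        label: [lib.counts[g] for g in guides]
        for label, lib in zip([*exp_labels, *ctrl_labels], [*experimental, *control])
    }
    original = pd.DataFrame(data, index=pd.Index(guides, name="guide"), dtype=np.int64)
    if (original.to_numpy() < 0).any():
        raise ValueError("negative counts")
    genes = reference.groups(by).reindex(guides)
    genes.name = by
    return CountMatrix(genes=genes, original=original,
                       exp_labels=exp_labels, ctrl_labels=ctrl_labels)


def impute(matrix: CountMatrix) -> CountMatrix:
    """Median imputation: missing -> 1, then ones -> per-gene, per-library median.

    Missing counts (zeros) are first set to one.  Then, in a single pass,
    every count equal to one — whether originally observed or just imputed —
    is replaced by the median of that gene's guide counts in the same
    library, computed from the pre-replacement values.  The substitution is
    not iterated: a gene whose guides are all 1 keeps median 1 and is a
    fixed point.  Medians over an even number of guides are the mean of the
    two central values.
    """
    counts = matrix.original.astype(float).where(matrix.original > 0, 1.0)
    medians = counts.groupby(matrix.genes, sort=False).transform("median")
    imputed = counts.where(counts != 1.0, medians)
    return dataclasses.replace(matrix, imputed=imputed)


def normalize(matrix: CountMatrix) -> CountMatrix:
    """Total normalization: divide each imputed count by its library's sum."""
    if matrix.imputed is None:
        raise ValueError("call impute() before normalize()")
    totals = matrix.imputed.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"empty libraries (total count 0): {empty}")
    return dataclasses.replace(matrix, normalized=matrix.imputed / totals)


def prepare(matrix: CountMatrix) -> CountMatrix:
    """Convenience: impute then normalize."""
    return normalize(impute(matrix))


@dataclass
class GeneResult:
    """Per-gene test result.

    ``ratios`` are the paired log2(experimental / control) frequency ratios,
    one per guide per replicate pair; ``t`` is m / (s / sqrt(n)) referred to
    the standard normal.  ``p`` is None for genes with a single ratio (a
    one-ratio z-test is undefined; such genes are excluded from multiple
    testing).  ``degenerate`` flags zero-variance genes whose t is +/-inf.
    """

    gene: str
    n: int
    ratios: np.ndarray
    mean: float
    sd: float
    t: float
    p: float | None
    guide_fraction: float
    degenerate: bool = False
    p_bh: float | None = None
    p_bonf: float | None = None


def _pvalue_from_t(t: np.ndarray, tail: str) -> np.ndarray:
    if tail == "enrichment":
        return stats.norm.sf(t)
    if tail == "depletion":
        return stats.norm.cdf(t)
    if tail == "two_sided":
        return 2.0 * stats.norm.sf(np.abs(t))
    raise ValueError(f"unknown tail {tail!r}; choose from {TAILS}")


def ztest_from_ratios(ratios: np.ndarray, tail: str = "enrichment") -> pd.DataFrame:
    """Vectorized mean/sd/t/p over rows of a (genes x ratios) matrix.

    Degenerate rows (sd = 0) get t = +/-inf by the sign of the mean, or
    t = 0, p = 0.5 (enrichment tail) when the mean is also 0.
    """
    r = np.asarray(ratios, dtype=float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise ValueError("ratios must be a 2-D array with at least two columns")
    n = r.shape[1]
    m = r.mean(axis=1)
    s = r.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    zero_s = s == 0.0
    t = np.where(zero_s & (m > 0), np.inf, t)
    t = np.where(zero_s & (m < 0), -np.inf, t)
    t = np.where(zero_s & (m == 0), 0.0, t)
    p = _pvalue_from_t(t, tail)
    return pd.DataFrame({"n": n, "mean": m, "sd": s, "t": t, "p": p})


def gene_ratios(matrix: CountMatrix, gene: str) -> np.ndarray:
    """Paired log2 frequency ratios for one gene, pooled across guides and
    replicate pairs (experimental library j vs control library j)."""
    if matrix.normalized is None:
        raise ValueError("matrix must be imputed and normalized first")
    guides = matrix.guides_of(gene)
    if not guides:
        raise KeyError(f"gene {gene!r} not in matrix")
    x = matrix.normalized.loc[guides]
    parts = [
        np.log2(x[e].to_numpy() / x[c].to_numpy())
        for e, c in zip(matrix.exp_labels, matrix.ctrl_labels)
    ]
    return np.concatenate(parts)


def _guide_fractions(matrix: CountMatrix) -> pd.Series:
    """Per-gene share of all mapped experimental reads (original counts)."""
    exp = matrix.original[matrix.exp_labels].sum(axis=1)
    total = exp.sum()
    per_gene = exp.groupby(matrix.genes, sort=False).sum()
    return per_gene / total if total > 0 else per_gene * 0.0


def gene_test(matrix: CountMatrix, gene: str, tail: str = "enrichment") -> GeneResult:
    """Test a single gene for enrichment/depletion of its guides."""
    r = gene_ratios(matrix, gene)
    n = len(r)
    frac = float(_guide_fractions(matrix).get(gene, 0.0))
    if n == 1:
        return GeneResult(gene=gene, n=1, ratios=r, mean=float(r[0]), sd=float("nan"),
                          t=float("nan"), p=None, guide_fraction=frac)
    row = ztest_from_ratios(r[None, :], tail=tail).iloc[0]
    return GeneResult(
        gene=gene, n=n, ratios=r, mean=float(row["mean"]), sd=float(row["sd"]),
        t=float(row["t"]), p=float(row["p"]), guide_fraction=frac,
        degenerate=bool(row["sd"] == 0.0),
    )


def score_genes(matrix: CountMatrix, tail: str = "enrichment") -> list[GeneResult]:
    """Test every gene; fills BH and Bonferroni adjusted p-values.

    The multiple-testing family size is the number of genes actually tested
    (those with at least two ratios), not a fixed genome-wide count.  Genes
    reduced to a single ratio are reported with their mean log2 fold change
    and no p-value.
    """
    if matrix.normalized is None:
        matrix = prepare(matrix)
    fractions = _guide_fractions(matrix)
    results: list[GeneResult] = []
    norm = matrix.normalized
    log2x = np.log2(norm.to_numpy())
    exp_idx = [norm.columns.get_loc(e) for e in matrix.exp_labels]
    ctrl_idx = [norm.columns.get_loc(c) for c in matrix.ctrl_labels]
    gene_codes, gene_order = pd.factorize(matrix.genes, sort=False)
    ratio_block = log2x[:, exp_idx] - log2x[:, ctrl_idx]  # guides x pairs
    for gi, gene in enumerate(gene_order):
        rows = np.nonzero(gene_codes == gi)[0]
        r = ratio_block[rows].ravel(order="F")  # guides within pair, pairs concatenated
        n = len(r)
        frac = float(fractions.get(gene, 0.0))
        if n == 0:
            continue
        if n == 1:
            results.append(GeneResult(gene=gene, n=1, ratios=r, mean=float(r[0]),
                                      sd=float("nan"), t=float("nan"), p=None,
                                      guide_fraction=frac))
            continue
        m = float(r.mean())
        s = float(r.std(ddof=1))
        if s == 0.0:
            t = float(np.inf) if m > 0 else (float(-np.inf) if m < 0 else 0.0)
            degenerate = True
        else:
            t = m / (s / np.sqrt(n))
            degenerate = False
        p = float(_pvalue_from_t(np.array([t]), tail)[0])
        results.append(GeneResult(gene=gene, n=n, ratios=r, mean=m, sd=s, t=t, p=p,
                                  guide_fraction=frac, degenerate=degenerate))
    tested = [res for res in results if res.p is not None]
    if tested:
        p_bh, p_bonf = adjust_pvalues(np.array([res.p for res in tested]))
        for res, bh, bonf in zip(tested, p_bh, p_bonf):
            res.p_bh = float(bh)
            res.p_bonf = float(bonf)
    return results


def results_frame(results: Sequence[GeneResult]) -> pd.DataFrame:
    """Tabular view of gene results, one row per gene."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "n_ratios": [r.n for r in results],
            "log2fc": [r.mean for r in results],
            "sd": [r.sd for r in results],
            "t": [r.t for r in results],
            "p": [r.p if r.p is not None else np.nan for r in results],
            "p_bh": [r.p_bh if r.p_bh is not None else np.nan for r in results],
            "p_bonf": [r.p_bonf if r.p_bonf is not None else np.nan for r in results],
            "guide_fraction": [r.guide_fraction for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )


def adjust_pvalues(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg and Bonferroni adjusted p-values.

    BH is the step-up procedure: sort ascending, scale p_(i) by m/i, take
    the cumulative minimum from the largest rank down, cap at 1.  Bonferroni
    is min(1, m*p).  Input values outside [0, 1] raise ValueError.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy(), p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    stepped = np.minimum.accumulate(ranked[::-1])[::-1]
    p_bh = np.empty(m)
    p_bh[order] = np.minimum(stepped, 1.0)
    p_bonf = np.minimum(p * m, 1.0)
    return p_bh, p_bonf


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Raw-p significance cutoff under Bonferroni control: alpha / m.

    For a genome-scale screen of about 20,000 genes at alpha = 0.05 this is
    0.05 / 20000 = 0.0000025.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie strictly between 0 and 1")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def volcano_data(
    results: Sequence[GeneResult],
    log_base: int = 2,
    alpha: float = 0.05,
    m: int | None = None,
) -> pd.DataFrame:
    """Volcano-plot table: x = mean log2FC, y = -log_base(p), significance flag.

    A gene is significant when its raw p falls below the Bonferroni
    threshold alpha/m (m defaults to the number of tested genes).  p = 0 is
    clamped to the smallest positive double and flagged.  Rows are sorted by
    p, then by |x| descending.
    """
    if log_base not in (2, 10):
        raise ValueError("log_base must be 2 or 10")
    tested = [r for r in results if r.p is not None]
    if m is None:
        m = len(tested)
    threshold = bonferroni_threshold(alpha, m) if tested else 0.0
    tiny = np.finfo(float).tiny
    rows = []
    for r in tested:
        clamped = r.p == 0.0
        p = tiny if clamped else r.p
        rows.append(
            {
                "gene": r.gene,
                "log2fc": r.mean,
                "neg_log_p": -np.log(p) / np.log(log_base),
                "p": r.p,
                "significant": r.p < threshold,
                "clamped": clamped,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "neg_log_p", "p", "significant", "clamped"])
    if len(df):
        df = df.sort_values(["p", "log2fc"], key=lambda s: s.abs() if s.name == "log2fc" else s,
                            ascending=[True, False]).reset_index(drop=True)
    return df


def volcano_plot(
    volcano: pd.DataFrame, path: str | Path, log_base: int = 2, title: str = ""
) -> None:
    """Static volcano plot; Bonferroni-significant genes drawn in red."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    insig = volcano[~volcano["significant"]]
    sig = volcano[volcano["significant"]]
    ax.scatter(insig["log2fc"], insig["neg_log_p"], s=8, c="0.6", label="n.s.")
    if len(sig):
        ax.scatter(sig["log2fc"], sig["neg_log_p"], s=12, c="red", label="Bonferroni sig.")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel(f"-log{log_base}(p)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def export_results(
    matrix: CountMatrix, results: Sequence[GeneResult], path: str | Path
) -> None:
    """Export per-gene counts and statistics as CSV.

    One row per gene: the gene identifier; then, for each guide slot and each
    library, the original, imputed and normalized counts; then the mean
    log2 fold change, raw p, BH FDR and Bonferroni-adjusted p.  Genes with
    fewer guides than the widest gene leave their surplus slots empty.
    Values are written with 12 significant digits so a read-back reproduces
    them.
    """
    if matrix.normalized is None or matrix.imputed is None:
        raise ValueError("matrix must be imputed and normalized before export")
    libraries = [*matrix.exp_labels, *matrix.ctrl_labels]
    max_guides = int(matrix.genes.groupby(matrix.genes, sort=False).size().max())
    header = ["gene"]
    for k in range(1, max_guides + 1):
        for lib in libraries:
            header += [f"guide{k}_{lib}_original", f"guide{k}_{lib}_imputed",
                       f"guide{k}_{lib}_normalized"]
    header += ["log2fc", "p", "p_bh", "p_bonf"]
    with open(path, "w") as out:
        out.write(",".join(header) + "\n")
        for res in results:
            guides = matrix.guides_of(res.gene)
            cells = [str(res.gene)]
            for k in range(max_guides):
                for lib in libraries:
                    if k < len(guides):
                        g = guides[k]
                        cells += [
                            str(int(matrix.original.at[g, lib])),
                            _fmt(matrix.imputed.at[g, lib]),
                            _fmt(matrix.normalized.at[g, lib]),
                        ]
                    else:
                        cells += ["", "", ""]
            cells.append(_fmt(res.mean))
            for value in (res.p, res.p_bh, res.p_bonf):
                cells.append("" if value is None else _fmt(value))
            out.write(",".join(cells) + "\n")
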