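"""Gene-set overlap and GWAS relative-rank enrichment statistics.

Two complementary questions are answered here.  First, do two gene lists
drawn from a common tested background (e.g. an aging signature and a
previously published one, or pQTL genes and a tissue's eQTL genes) share
more members than independence predicts?  That is a 2x2 exact test, with
the expected overlap |A||B|/N, the sample (cross-product) odds ratio and
the fold enrichment observed/expected reported alongside the two-sided
hypergeometric p.  Second, do the SNPs underlying pQTL signals (pSNPs)
sit unusually high in an external GWAS ranking?  The GWAS table is
reduced to the SNPs covered by the pQTL study, each SNP's p-value is
converted to its relative rank in the reduced table (best = 1/M), and
the pSNPs' relative ranks are compared with the uniform distribution via
a rank-rank (-log10) plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .core_io import GeneSet, GwasTable, logger

#: default background size for signature-overlap tests: distinct tested
#: gene symbols on the assay (configurable per call)
DEFAULT_BACKGROUND_N = 1126


@dataclass
class OverlapResult:
    """Overlap of two gene sets on a background of ``background_n`` genes."""

    observed: int
    expected: float
    odds_ratio: float          # sample (cross-product) OR; inf when b*c == 0
    odds_ratio_cmle: float     # conditional-MLE OR (secondary)
    fold_enrichment: float
    p: float
    background_n: int
    table: tuple               # (a, b, c, d)
    infinite_or: bool = False


def overlap_test(
    set_a: GeneSet,
    set_b: GeneSet,
    background: GeneSet | int = DEFAULT_BACKGROUND_N,
) -> OverlapResult:
    """Background-conditioned overlap test between two gene sets.

    ``background`` is either the explicit background gene set (members of
    A/B outside it are dropped with a warning) or just its size, in which
    case both sets are assumed to lie inside it.  The 2x2 table is
    a = |A n B|, b = |B \\ A|, c = |A \\ B|, d = N - a - b - c; the exact p
    is two-sided in the usual sense (all tables with point probability at
    most that of the observed one).
    """
    a_set, b_set = set(set_a.members), set(set_b.members)
    if isinstance(background, GeneSet):
        bg = set(background.members)
        n_bg = len(bg)
        for label, s in ((set_a.label, a_set), (set_b.label, b_set)):
            out = s - bg
            if out:
                logger.warning("dropping %d genes of %s outside the background: %s",
                               len(out), label, sorted(out)[:5])
        a_set &= bg
        b_set &= bg
    else:
        n_bg = int(background)
    a = len(a_set & b_set)
    b = len(b_set - a_set)
    c = len(a_set - b_set)
    d = n_bg - a - b - c
    if d < 0:
        raise ValueError(
            f"background size {n_bg} smaller than the union of the sets ({a + b + c})"
        )
    expected = len(a_set) * len(b_set) / n_bg if n_bg else 0.0
    fold = a / expected if expected > 0 else 0.0
    infinite = False
    if b * c == 0:
        orr = np.inf if a * d > 0 else 0.0
        infinite = a * d > 0
    else:
        orr = (a * d) / (b * c)
    table = [[a, b], [c, d]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    cmle = float(_odds_ratio(table, kind="conditional").statistic)
    return OverlapResult(
        observed=a, expected=expected, odds_ratio=float(orr),
        odds_ratio_cmle=cmle, fold_enrichment=float(fold), p=p,
        background_n=n_bg, table=(a, b, c, d), infinite_or=infinite,
    )


@dataclass
class RankEnrichment:
    """Relative ranks of pSNPs within a reduced GWAS table."""

    relative_ranks: np.ndarray   # in (0, 1], aligned with variant_ids
    variant_ids: list
    reduced_table_size: int

    @property
    def n_hits(self) -> int:
        return len(self.relative_ranks)

    def qq_data(self) -> pd.DataFrame:
        """Expected-vs-observed -log10(relative rank) pairs for a rank-rank
        plot; expected ranks are the uniform order statistics i/(k+1)."""
        obs = np.sort(self.relative_ranks)
        k = len(obs)
        exp = np.arange(1, k + 1) / (k + 1)
        return pd.DataFrame(
            {"expected_neglog10": -np.log10(exp), "observed_neglog10": -np.log10(obs)}
        )

    def plot(self, path) -> None:
        """Write the rank-rank plot (observed vs expected -log10 relative rank)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        qq = self.qq_data()
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.plot(qq["expected_neglog10"], qq["observed_neglog10"], "o", ms=3)
        lim = max(qq.to_numpy().max(), 1.0)
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("expected -log10(relative rank)")
        ax.set_ylabel("observed -log10(relative rank)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def gwas_rank_enrichment(
    psnp_ids: list[str],
    gwas: GwasTable,
    covered: list[str],
) -> RankEnrichment:
    """Relative ranks of pSNPs within the GWAS table reduced to covered SNPs.

    The table is first restricted to ``covered`` (the variants assayed by
    the pQTL study), p-values are ranked ascending with average ranks on
    ties, and each pSNP's relative rank is rank / reduced-table size.
    pSNPs absent from the reduced table are dropped with a warning; an
    empty intersection is an error.
    """
    covered_set = set(covered)
    reduced = gwas.df[gwas.df["variant_id"].isin(covered_set)]
    if len(reduced) == 0:
        raise ValueError("no GWAS variants covered by the pQTL study")
    m = len(reduced)
    rel = pd.Series(
        stats.rankdata(reduced["p"].to_numpy(), method="average") / m,
        index=reduced["variant_id"].to_numpy(),
    )
    present = [v for v in psnp_ids if v in rel.index]
    absent = set(psnp_ids) - set(present)
    if absent:
        logger.warning("dropping %d pSNPs absent from the reduced GWAS table: %s",
                       len(absent), sorted(absent)[:5])
    if not present:
        raise ValueError("no pSNP overlaps the reduced GWAS table")
    return RankEnrichment(
        relative_ranks=rel.loc[present].to_numpy(),
        variant_ids=present,
        reduced_table_size=m,
    )


def select_psnps(result: pd.DataFrame, p_cutoff: float = 1e-5) -> list[str]:
    """Unique variant ids of scan pairs with p <= cutoff (closed threshold)."""
    hits = result[result["p"].notna() & (result["p"] <= p_cutoff)]
    return sorted(hits["variant_id"].unique())
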