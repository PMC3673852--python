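"""Model/Results interface tying the analysis pipeline together.

`SeparateChannelModel` holds the data and design; `fit()` estimates the
common intra-spot correlation (unless supplied), rescales to the
homoscedastic form, runs the gene-wise least squares and empirical Bayes
moderation, and returns a `SeparateChannelResults` object carrying the
estimates, their uncertainties and a `summary()` table.  The traditional
log-ratio analysis is available through ``method="log_ratio"`` for direct
comparison on the same data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import ebayes as _ebayes
from . import het_reml as _het_reml
from .correlation import CorrelationEstimate, estimate_common_correlation
from .io_design import ChannelDesign, ContrastMatrix, TargetsTable, TwoChannelMatrix, build_channel_design, make_contrasts, read_targets, read_two_channel
from .linear_model import LinearFitSet, contrast_fit, fit_gene_lm, fit_log_ratio, rescale_ma
from .ma import MAData, normalize_a_quantile, normalize_m_loess, to_ma, transform_design

__all__ = ["SeparateChannelModel", "SeparateChannelResults"]


class SeparateChannelModel:
    """Gene-wise linear model for two-colour arrays using both channels.

    Parameters
    ----------
    data : TwoChannelMatrix or MAData
        Normalized log2 intensities (or their M/A representation).
    targets : TargetsTable
        Condition hybridized to each channel of each array.
    contrasts : list of str, optional
        Contrast specifications like ``"BvsC = B - C"``; if omitted the
        condition coefficients themselves are tested.
    dye_effect : bool
        Add an additive red-channel indicator column to the design.

    Examples
    --------
    >>> y, targets, truth = simulate_two_channel(SimConfig(seed=1))
    >>> model = SeparateChannelModel(y, targets, contrasts=["BvsC = B - C"])
    >>> res = model.fit()
    >>> res.correlation.rho  # doctest: +SKIP
    0.85...
    """

    def __init__(
        self,
        data: TwoChannelMatrix | MAData,
        targets: TargetsTable,
        contrasts: list | None = None,
        dye_effect: bool | None = None,
    ) -> None:
        if isinstance(data, TwoChannelMatrix):
            self.ma = to_ma(data)
        elif isinstance(data, MAData):
            self.ma = data
        else:
            raise TypeError("data must be a TwoChannelMatrix or MAData")
        if self.ma.n_arrays != targets.n_arrays:
            raise ValueError("data and targets disagree on the number of arrays")
        self.targets = targets
        self.design: ChannelDesign = build_channel_design(targets, dye_effect=dye_effect)
        self.transformed = transform_design(self.design)
        self.contrasts: ContrastMatrix | None = (
            make_contrasts(self.design, contrasts) if contrasts else None
        )

    @classmethod
    def from_files(
        cls,
        path_green,
        path_red,
        path_targets,
        contrasts: list | None = None,
        normalize: bool = False,
        loess_span: float = 0.3,
    ) -> "SeparateChannelModel":
        """Build a model straight from the TSV intensity and targets files."""
        y = read_two_channel(path_green, path_red)
        targets = read_targets(path_targets)
        ma = to_ma(y)
        if normalize:
            ma = normalize_a_quantile(normalize_m_loess(ma, span=loess_span))
        return cls(ma, targets, contrasts=contrasts)

    def estimate_correlation(self, trim: float = 0.15) -> CorrelationEstimate:
        """Per-gene two-stratum REML pooled into the common correlation."""
        fits = _het_reml.fit_all_genes(self.ma, self.transformed)
        self.gene_het_fits = fits
        return estimate_common_correlation(fits, trim=trim)

    def fit(
        self,
        rho: float | None = None,
        method: str = "separate_channel",
        moderate: bool = True,
        trim: float = 0.15,
    ) -> "SeparateChannelResults":
        """Run the full pipeline and return a results object.

        ``rho=None`` estimates the common intra-spot correlation from the
        data first (the usual workflow); a float fixes it.  With
        ``method="log_ratio"`` the M-only analysis is run instead and rho is
        not needed.  ``moderate=False`` skips the empirical Bayes step and
        reports ordinary t statistics.
        """
        correlation = None
        if method == "separate_channel":
            if rho is None:
                correlation = self.estimate_correlation(trim=trim)
                rho = correlation.rho
            z_star, Z_star = rescale_ma(self.ma, self.transformed, rho)
            lm = fit_gene_lm(z_star, Z_star, probes=list(self.ma.probes))
        elif method == "log_ratio":
            lm = fit_log_ratio(self.ma, self.targets, design=self.design)
        else:
            raise ValueError(f"unknown method {method!r}")
        if self.contrasts is not None:
            lm = contrast_fit(lm, self.contrasts)
        if moderate:
            eb = _ebayes.moderated_t(lm)
        else:
            t = lm.beta / (lm.sigma[:, None] * lm.stdev_unscaled[None, :])
            p = 2.0 * stats.t.sf(np.abs(t), lm.df_residual)
            q = np.column_stack(
                [_ebayes.bh_adjust(p[:, j]) for j in range(p.shape[1])]
            )
            eb = _ebayes.EBayesResult(
                s_tilde_2=lm.sigma**2,
                t=t,
                p=p,
                df_total=lm.df_residual,
                q=q,
                prior=_ebayes.VariancePrior(d0=1e-12, s0_2=1.0),
                coef_names=list(lm.coef_names),
                beta=lm.beta,
                probes=lm.probes,
            )
        pi0 = {
            name: _ebayes.storey_pi0(eb.p[:, j])
            for j, name in enumerate(eb.coef_names)
        }
        return SeparateChannelResults(
            model=self,
            method=method,
            rho=rho,
            correlation=correlation,
            lm=lm,
            eb=eb,
            pi0=pi0,
            moderated=moderate,
        )


@dataclass
class SeparateChannelResults:
    """Fitted pipeline results with per-gene statistics and diagnostics."""

    model: SeparateChannelModel
    method: str
    rho: float | None
    correlation: CorrelationEstimate | None
    lm: LinearFitSet
    eb: _ebayes.EBayesResult
    pi0: dict
    moderated: bool = True

    @property
    def coef_names(self) -> list:
        return list(self.lm.coef_names)

    def top_table(self, coef=0, n: int | None = None, sort_by: str = "p") -> pd.DataFrame:
        return _ebayes.top_table(self.eb, coef=coef, n=n, sort_by=sort_by)

    def n_significant(self, coef=0, fdr: float = 0.05) -> int:
        """Number of genes with BH-adjusted q below ``fdr`` for one contrast."""
        tab = self.top_table(coef=coef)
        return int((tab["q"] < fdr).sum())

    def summary(self) -> str:
        eb = self.eb
        lines = []
        title = (
            "Separate-channel linear model (common intra-spot correlation)"
            if self.method == "separate_channel"
            else "Log-ratio (M-value) linear model"
        )
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"Probes: {self.lm.beta.shape[0]}    Arrays: {self.model.ma.n_arrays}")
        if self.method == "separate_channel":
            src = "estimated" if self.correlation is not None else "supplied"
            lines.append(f"Intra-spot correlation rho = {self.rho:.4f} ({src})")
            if self.correlation is not None:
                c = self.correlation
                lines.append(
                    f"  pooled from {c.genes_used} genes, trim {c.trim:.0%}, "
                    f"tau = {c.tau:.4f}"
                )
        lines.append(f"Residual df per gene: {self.lm.df_residual:g}")
        if self.moderated:
            d0 = eb.prior.d0
            d0s = "inf" if math.isinf(d0) else f"{d0:.3f}"
            lines.append(
                f"Variance prior: d0 = {d0s}, s0^2 = {eb.prior.s0_2:.4f}; "
                f"moderated t on {eb.df_total:g} df"
            )
        else:
            lines.append("No variance moderation (ordinary t statistics)")
        header = f"{'contrast':>12} {'#q<0.05':>8} {'#q<0.01':>8} {'pi0':>6}"
        lines.append(header)
        for j, name in enumerate(eb.coef_names):
            n05 = int((eb.q[:, j] < 0.05).sum())
            n01 = int((eb.q[:, j] < 0.01).sum())
            lines.append(f"{name:>12} {n05:>8} {n01:>8} {self.pi0[name]:>6.2f}")
        return "\n".join(lines)
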