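"""Repeated-measures and mixed ANOVA with partial eta squared.

Thin wrappers over pingouin that enforce the complete within-participant
design, attach partial eta squared and the study's significance labelling
(within-participant effects significant at p < 0.005, trends at p < 0.05;
between-participant effects at 0.05), and expose Bonferroni-corrected
pairwise comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pingouin as pg

from .config import AnalysisConfig


class IncompleteDesignError(ValueError):
    """Raised when a within design has missing cells."""


def _check_complete(data: pd.DataFrame, dv: str, within: list[str], subject: str) -> None:
    counts = data.groupby([subject, *within], observed=True)[dv].count()
    if (counts < 1).any() or counts.isna().any():
        raise IncompleteDesignError("design has empty cells")
    per_subj = data.groupby(subject, observed=True).apply(
        lambda g: g.groupby(within, observed=True)[dv].count().shape[0],
        include_groups=False)
    full = int(np.prod([data[w].nunique() for w in within]))
    if (per_subj != full).any():
        raise IncompleteDesignError("not every participant covers every cell")


def _label(p: float, cfg: AnalysisConfig, between: bool = False) -> str:
    if between:
        return "significant" if p < cfg.alpha_between else "ns"
    if p < cfg.alpha_within:
        return "significant"
    if p < cfg.alpha_trend:
        return "trend"
    return "ns"


def rm_anova(data: pd.DataFrame, dv: str, within: list[str] | str,
             subject: str = "participant",
             config: AnalysisConfig | None = None) -> pd.DataFrame:
    """One- or two-way repeated-measures ANOVA (F, dof, p, partial eta^2)."""
    config = config or AnalysisConfig()
    within = [within] if isinstance(within, str) else list(within)
    _check_complete(data, dv, within, subject)
    aov = pg.rm_anova(data=data, dv=dv, within=within, subject=subject,
                      detailed=True, effsize="np2")
    aov = aov.rename(columns={"p-unc": "p", "p_unc": "p", "np2": "partial_eta_sq"})
    aov = aov[aov["Source"] != "Error"].copy()
    aov["significance"] = [_label(p, config) for p in aov["p"]]
    return aov.reset_index(drop=True)


def mixed_anova(data: pd.DataFrame, dv: str, within: str, between: str,
                subject: str = "participant",
                config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Mixed ANOVA (within factor x between-participant factor)."""
    config = config or AnalysisConfig()
    _check_complete(data, dv, [within], subject)
    aov = pg.mixed_anova(data=data, dv=dv, within=within, between=between,
                         subject=subject, effsize="np2")
    aov = aov.rename(columns={"p-unc": "p", "p_unc": "p", "np2": "partial_eta_sq"})
    aov["significance"] = [
        _label(p, config, between=(src != within))
        for p, src in zip(aov["p"], aov["Source"])]
    return aov


def pairwise_bonferroni(data: pd.DataFrame, dv: str, within: list[str] | str,
                        subject: str = "participant",
                        config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Post-hoc pairwise comparisons with Bonferroni correction."""
    config = config or AnalysisConfig()
    within = [within] if isinstance(within, str) else list(within)
    pw = pg.pairwise_tests(data=data, dv=dv, within=within, subject=subject,
                           padjust="bonf")
    pcol = next(c for c in ("p-corr", "p_corr", "p-unc", "p_unc") if c in pw.columns)
    pw = pw.rename(columns={pcol: "p_corrected"})
    pw["significance"] = [_label(p, config) for p in pw["p_corrected"]]
    return pw
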