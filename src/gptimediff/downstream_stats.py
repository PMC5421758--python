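"""Downstream statistics: comparative-Ct quantification and a Pearson
correlation screen of expression against drug response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .difftest import bh_adjust


@dataclass(frozen=True)
class CtRecord:
    """qPCR cycle-threshold values for one target gene and the endogenous
    reference, in a treated and a calibrator (control) sample."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self):
        for name, val in self.__dict__.items():
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{name} must be finite and positive, got {val!r}")


@dataclass(frozen=True)
class RelativeQuantification:
    delta_ct_treated: float
    delta_ct_control: float
    ddct: float
    rq: float


def relative_quantification(record: CtRecord) -> RelativeQuantification:
    """Comparative-Ct method: dCt = Ct(target) - Ct(reference) per sample,
    ddCt = dCt(treated) - dCt(control), RQ = 2^(-ddCt)."""
    d_treated = record.ct_target_treated - record.ct_ref_treated
    d_control = record.ct_target_control - record.ct_ref_control
    ddct = d_treated - d_control
    return RelativeQuantification(
        delta_ct_treated=d_treated,
        delta_ct_control=d_control,
        ddct=ddct,
        rq=float(2.0 ** (-ddct)),
    )


def correlation_screen(expression: pd.DataFrame, responses: pd.DataFrame,
                       fdr_levels=(0.1,)):
    """Pearson correlation of each gene's expression with each drug's
    response over shared samples.

    ``expression``: genes x samples; ``responses``: samples x drugs (e.g.
    area under the dose-response curve).  Missing values are handled by
    pairwise-complete deletion; pairs with fewer than 3 complete samples or
    zero variance are flagged (r/p/q = NaN) and excluded from FDR.  q-values
    are BH-adjusted per drug.

    Returns ``(table, summary)``: the per-(gene, drug) table with columns
    gene, drug, n, r, p, q, flagged; and per-drug counts of genes significant
    at raw p < 0.05 and at each BH FDR level.
    """
    shared = [s for s in expression.columns if s in responses.index]
    if not shared:
        raise ValueError("no shared samples between expression and responses")
    rows = []
    for drug in responses.columns:
        resp = responses.loc[shared, drug].to_numpy(dtype=float)
        for gene in expression.index:
            expr = expression.loc[gene, shared].to_numpy(dtype=float)
            ok = np.isfinite(expr) & np.isfinite(resp)
            n = int(ok.sum())
            flagged = n < 3 or np.std(expr[ok]) == 0 or np.std(resp[ok]) == 0
            if flagged:
                r = p = np.nan
            else:
                r, p = stats.pearsonr(expr[ok], resp[ok])
            rows.append({"gene": gene, "drug": drug, "n": n,
                         "r": float(r), "p": float(p), "flagged": flagged})
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for drug, grp in table.groupby("drug"):
        valid = grp.index[~grp["flagged"]]
        if len(valid):
            q, _ = bh_adjust(table.loc[valid, "p"], 0.05)
            table.loc[valid, "q"] = q

    summary_rows = []
    for drug, grp in table.groupby("drug"):
        valid = grp[~grp["flagged"]]
        row = {"drug": drug, "n_tested": len(valid),
               "n_p_lt_0.05": int((valid["p"] < 0.05).sum())}
        for level in fdr_levels:
            row[f"n_fdr_{level:g}"] = int((valid["q"] <= level).sum())
        summary_rows.append(row)
    return table, pd.DataFrame(summary_rows)
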