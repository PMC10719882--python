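"""Publication-style summary tables.

Two tables mirror the standard comparative-GWAS reporting layout: a PVE
comparison (narrow-sense SNP heritability from the null LMM next to the
BSLMM PVE of every analysis) and a hyperparameter grid (PVE, PGE, Rho,
Pi, N.Gamma per analysis, each as a point estimate with a 2.5–97.5%
interval).  PVE, PGE and Pi are formatted on the 0–100% scale;
Manhattan-style per-SNP data files carry −log10 P for the LMM and
PIP plus |β × γ| for the BSLMM, so plots can be drawn from plain text.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bslmm import BslmmPosterior
from .lmm import LmmSnpResult, ScanThresholds

__all__ = ["render_tables", "manhattan_lmm", "manhattan_bslmm"]

_PERCENT = {"pve", "pge", "pi"}


def _fmt(name: str, value: float) -> float:
    return round(100.0 * value, 3) if name in _PERCENT else round(value, 4)


def render_tables(
    posteriors: dict[str, BslmmPosterior],
    lmm_h2: tuple[float, tuple[float, float]] | None = None,
    mass: float = 0.95,
    mode: str = "central",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the PVE-comparison and hyperparameter tables.

    ``posteriors`` maps analysis name (e.g. "GWA", "p_values_1pct") to a
    fitted posterior; ``lmm_h2`` is the null-model heritability estimate
    with its confidence interval.  Returns (pve_table, hyper_table);
    intervals always contain their point estimates.
    """
    if not posteriors and lmm_h2 is None:
        raise ValueError("nothing to tabulate")
    pve_rows = []
    if lmm_h2 is not None:
        h2, (lo, hi) = lmm_h2
        pve_rows.append(
            {"analysis": "LMM (h2_SNP)", "estimate_pct": _fmt("pve", h2),
             "lo_pct": _fmt("pve", lo), "hi_pct": _fmt("pve", hi)}
        )
    hyper_rows = []
    for name, post in posteriors.items():
        row = {"analysis": name}
        for hp in ("pve", "pge", "rho", "pi", "n_gamma"):
            est = post.point_estimate(hp)
            lo, hi = post.hyperparameter_interval(hp, mass=mass, mode=mode)
            lo, hi = min(lo, est), max(hi, est)
            row[hp] = _fmt(hp, est)
            row[f"{hp}_lo"] = _fmt(hp, lo)
            row[f"{hp}_hi"] = _fmt(hp, hi)
        hyper_rows.append(row)
        est = post.point_estimate("pve")
        lo, hi = post.hyperparameter_interval("pve", mass=mass, mode=mode)
        pve_rows.append(
            {"analysis": f"BSLMM {name} (PVE)", "estimate_pct": _fmt("pve", est),
             "lo_pct": _fmt("pve", min(lo, est)), "hi_pct": _fmt("pve", max(hi, est))}
        )
    return pd.DataFrame(pve_rows), pd.DataFrame(hyper_rows)


def manhattan_lmm(results: list[LmmSnpResult], thresholds: ScanThresholds) -> pd.DataFrame:
    """Per-SNP −log10 P with the Gao and suggestive lines as columns."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in results],
            "pos": [r.pos for r in results],
            "id": [r.snp_id for r in results],
            "neg_log10_p": [-np.log10(max(r.p_wald, 5e-324)) for r in results],
            "gao_line": thresholds.significant_logp,
            "suggestive_line": thresholds.suggestive_logp,
        }
    )


def manhattan_bslmm(post: BslmmPosterior) -> pd.DataFrame:
    """Per-SNP PIP and sparse effect |β × γ| plus its share of the total
    summed sparse effect (relative effect size, %)."""
    eff = post.sparse_effects()
    total = eff.sum()
    rel = 100.0 * eff / total if total > 0 else np.zeros_like(eff)
    return pd.DataFrame(
        {
            "chrom": post.chroms,
            "pos": post.positions,
            "id": post.snp_ids,
            "pip": post.pip,
            "sparse_effect": eff,
            "relative_effect_pct": rel,
        }
    )
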