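"""Certainty binning, mixed-effects certainty models with likelihood-ratio
tests, and scalp-topography correlation comparison.

The dependent variable is always log2(SNR) over the 30-electrode
posterior ROI.  Three nested model levels are supported: per frequency,
per frequency category (pooling that category's frequencies), and
between categories (certainty x category interaction).  Significance of
a term is a likelihood-ratio test between maximum-likelihood fits of the
full and reduced models; p-values across a tested family are adjusted
with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .montage import POSTERIOR_ROI

__all__ = [
    "CertaintyBin",
    "LMEResult",
    "TopoComparison",
    "certainty_bin",
    "fdr_adjust",
    "fit_certainty_effect",
    "interaction_contrast",
    "topo_correlation_compare",
]


@dataclass(frozen=True)
class CertaintyBin:
    """One of ten 5-percentage-point certainty bins."""

    index: int  # 1 (lowest certainty) .. 10 (highest)
    lo_pct: float
    hi_pct: float


def certainty_bin(p_dominant: float) -> CertaintyBin:
    """Bin a dominant-image proportion in [0.5, 1] into bins 1..10.

    Intervals are left-closed ([50, 55) -> 1, [55, 60) -> 2, ...);
    p = 1.0 belongs to bin 10.
    """
    if not (0.5 - 1e-12 <= p_dominant <= 1.0 + 1e-12):
        raise ValueError("p_dominant must lie in [0.5, 1]")
    pct = p_dominant * 100.0
    idx = int(np.floor((pct - 50.0 + 1e-9) / 5.0)) + 1
    idx = min(max(idx, 1), 10)
    return CertaintyBin(index=idx, lo_pct=50.0 + 5.0 * (idx - 1), hi_pct=50.0 + 5.0 * idx)


@dataclass
class LMEResult:
    """Likelihood-ratio test of one fixed-effect term."""

    level: str  # "frequency" | "category" | "interaction"
    selector: str  # which frequency/category (or contrast) was tested
    term: str
    estimate: float
    direction: str  # "+", "-" or "0"
    chi2: float
    df: int
    p_raw: float
    p_fdr: float | None = None
    converged: bool = True


def _prepare(
    df: pd.DataFrame, predictor: str, roi: tuple[str, ...] | None
) -> pd.DataFrame:
    required = {"participant", "channel", "frequency", "role", "snr", "certainty"}
    if not required.issubset(df.columns):
        raise ValueError(f"need columns {sorted(required)}")
    if (df["snr"] <= 0).any():
        raise ValueError("SNR values must be positive for the log2 transform")
    out = df.copy()
    if roi:
        out = out[out["channel"].isin(roi)]
        if out.empty:
            raise ValueError("no ROI channels present in the table")
    out["log2snr"] = np.log2(out["snr"])
    if predictor == "bin":
        out["certainty_x"] = [float(certainty_bin(p).index) for p in out["certainty"]]
    elif predictor == "proportion":
        out["certainty_x"] = out["certainty"].astype(float)
    else:
        raise ValueError("predictor must be 'bin' or 'proportion'")
    return out


def _vc(random_structure: str, with_frequency: bool) -> dict[str, str]:
    vc = {"channel": "0 + C(channel)"}
    if random_structure == "full":
        vc["channel_slope"] = "0 + C(channel):certainty_x"
    if with_frequency:
        vc["frequency"] = "0 + C(frequency)"
        if random_structure == "full":
            vc["frequency_slope"] = "0 + C(frequency):certainty_x"
    return vc


def _fit_ml(formula: str, data: pd.DataFrame, vc: dict[str, str]):
    """ML fit of a mixed model; retries with a simpler optimiser, then with
    diagonal-only random effects when the fit is singular."""
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            formula,
            data,
            groups=data["participant"],
            re_formula="1 + certainty_x",
            vc_formula=vc,
        )
        # gradient-based optimisers frequently stall on these profiles;
        # direct-search methods are slower per step but reliable, so try
        # both and keep the best ML solution
        for method in ("powell", "lbfgs", "nm"):
            try:
                fit = model.fit(reml=False, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(fit.llf) and (best is None or fit.llf > best.llf):
                best = fit
            if best is not None and best.converged:
                break
        if best is not None:
            return best
        # last resort: intercept-only participant random effect
        model = MixedLM.from_formula(
            formula, data, groups=data["participant"], vc_formula=vc
        )
        return model.fit(reml=False, method="powell", maxiter=500)


def _lrt(full, reduced, df: int) -> tuple[float, float]:
    chi2 = max(2.0 * (full.llf - reduced.llf), 0.0)
    return chi2, float(spstats.chi2.sf(chi2, df))


def fit_certainty_effect(
    snr_df: pd.DataFrame,
    *,
    level: str = "frequency",
    frequency: float | None = None,
    category: str | None = None,
    predictor: str = "bin",
    random_structure: str = "full",
    roi: tuple[str, ...] | None = POSTERIOR_ROI,
) -> LMEResult:
    """Likelihood-ratio test for the certainty effect at one model level.

    level="frequency": single frequency of interest (pass ``frequency``);
    random effects are channel nested in participant.
    level="category": one frequency category (pass ``category``, e.g.
    "im"); adds frequency nested in channel nested in participant.
    level="interaction": certainty x category across all categories in
    the table; the interaction term is tested.

    ``random_structure="full"`` gives every random term a slope as well
    as an intercept; ``"fast"`` keeps intercepts only for the
    variance-component terms (participants keep their random slope).
    """
    data = _prepare(snr_df, predictor, roi)
    if level == "frequency":
        if frequency is None:
            raise ValueError("level='frequency' requires a frequency")
        data = data[np.isclose(data["frequency"], frequency)]
        if data.empty:
            raise ValueError(f"no rows at frequency {frequency}")
        vc = _vc(random_structure, with_frequency=False)
        full = _fit_ml("log2snr ~ certainty_x", data, vc)
        reduced = _fit_ml("log2snr ~ 1", data, vc)
        chi2, p = _lrt(full, reduced, 1)
        est = float(full.params["certainty_x"])
        return LMEResult(
            level=level,
            selector=f"{frequency:g} Hz",
            term="certainty",
            estimate=est,
            direction="+" if est > 0 else ("-" if est < 0 else "0"),
            chi2=chi2,
            df=1,
            p_raw=p,
            converged=bool(full.converged and reduced.converged),
        )
    if level == "category":
        if category is None:
            raise ValueError("level='category' requires a category")
        data = data[data["role"] == category]
        if data.empty:
            raise ValueError(f"no rows in category {category!r}")
        multi_freq = data["frequency"].nunique() > 1
        vc = _vc(random_structure, with_frequency=multi_freq)
        full = _fit_ml("log2snr ~ certainty_x", data, vc)
        reduced = _fit_ml("log2snr ~ 1", data, vc)
        chi2, p = _lrt(full, reduced, 1)
        est = float(full.params["certainty_x"])
        return LMEResult(
            level=level,
            selector=category,
            term="certainty",
            estimate=est,
            direction="+" if est > 0 else ("-" if est < 0 else "0"),
            chi2=chi2,
            df=1,
            p_raw=p,
            converged=bool(full.converged and reduced.converged),
        )
    if level == "interaction":
        cats = sorted(data["role"].unique())
        if len(cats) < 2:
            raise ValueError("interaction level needs at least two categories")
        ref = "ssvep" if "ssvep" in cats else cats[0]
        vc = _vc(random_structure, with_frequency=data["frequency"].nunique() > 1)
        base = f"C(role, Treatment('{ref}'))"
        full = _fit_ml(f"log2snr ~ certainty_x * {base}", data, vc)
        reduced = _fit_ml(f"log2snr ~ certainty_x + {base}", data, vc)
        df_term = len(cats) - 1
        chi2, p = _lrt(full, reduced, df_term)
        inter = [k for k in full.params.index if ":certainty_x" in k or "certainty_x:" in k]
        est = float(np.mean([full.params[k] for k in inter])) if inter else 0.0
        return LMEResult(
            level=level,
            selector="x".join(cats),
            term="certainty:category",
            estimate=est,
            direction="+" if est > 0 else ("-" if est < 0 else "0"),
            chi2=chi2,
            df=df_term,
            p_raw=p,
            converged=bool(full.converged and reduced.converged),
        )
    raise ValueError("level must be 'frequency', 'category' or 'interaction'")


def interaction_contrast(
    snr_df: pd.DataFrame,
    category: str,
    reference: str = "ssvep",
    *,
    predictor: str = "bin",
    random_structure: str = "full",
    roi: tuple[str, ...] | None = POSTERIOR_ROI,
) -> LMEResult:
    """Certainty-slope contrast of one category against a reference.

    Fits the interaction model on the two categories only and tests the
    certainty x category term (1 df).  A positive direction means the
    tested category's certainty slope exceeds the reference's.
    """
    data = _prepare(snr_df, predictor, roi)
    data = data[data["role"].isin([category, reference])]
    if data["role"].nunique() != 2:
        raise ValueError(f"need both {category!r} and {reference!r} in the table")
    vc = _vc(random_structure, with_frequency=data["frequency"].nunique() > 1)
    base = f"C(role, Treatment('{reference}'))"
    full = _fit_ml(f"log2snr ~ certainty_x * {base}", data, vc)
    reduced = _fit_ml(f"log2snr ~ certainty_x + {base}", data, vc)
    chi2, p = _lrt(full, reduced, 1)
    inter = [k for k in full.params.index if "certainty_x:" in k]
    est = float(full.params[inter[0]]) if inter else 0.0
    return LMEResult(
        level="interaction",
        selector=f"{category} vs {reference}",
        term="certainty:category",
        estimate=est,
        direction="+" if est > 0 else ("-" if est < 0 else "0"),
        chi2=chi2,
        df=1,
        p_raw=p,
        converged=bool(full.converged and reduced.converged),
    )


def fdr_adjust(results: list[LMEResult], alpha: float = 0.05) -> list[LMEResult]:
    """Benjamini-Hochberg adjustment across a family of LRT results."""
    if not results:
        return []
    _, p_fdr, _, _ = multipletests([r.p_raw for r in results], alpha=alpha, method="fdr_bh")
    return [replace(r, p_fdr=float(q)) for r, q in zip(results, p_fdr)]


@dataclass
class TopoComparison:
    """Fisher r-to-z comparison of an IM scalp map against two references."""

    r_im_ssvep: float
    r_im_swift: float
    z: float
    p: float
    n_channels: int


def topo_correlation_compare(
    im_map: np.ndarray, ssvep_map: np.ndarray, swift_map: np.ndarray
) -> TopoComparison:
    """Is an IM scalp map closer to the SSVEP map than to the SWIFT map?

    Pearson correlations across channels, Fisher-transformed, compared
    with z = (z1 - z2) / sqrt(2 / (n - 3)); two-tailed p.  Positive z
    means the IM topography resembles the SSVEP topography more.
    """
    im_map = np.asarray(im_map, float)
    ssvep_map = np.asarray(ssvep_map, float)
    swift_map = np.asarray(swift_map, float)
    n = im_map.size
    if ssvep_map.size != n or swift_map.size != n:
        raise ValueError("maps must share the channel set")
    if n < 4:
        raise ValueError("need at least 4 channels")
    for m in (im_map, ssvep_map, swift_map):
        if np.std(m) == 0:
            raise ValueError("zero-variance map: correlation undefined")
    r1 = float(np.corrcoef(im_map, ssvep_map)[0, 1])
    r2 = float(np.corrcoef(im_map, swift_map)[0, 1])
    if np.isclose(abs(r1), 1.0) and np.isclose(abs(r2), 1.0) and np.isclose(r1, r2):
        z = 0.0
    else:
        z1 = np.arctanh(np.clip(r1, -1 + 1e-15, 1 - 1e-15))
        z2 = np.arctanh(np.clip(r2, -1 + 1e-15, 1 - 1e-15))
        z = float((z1 - z2) / np.sqrt(2.0 / (n - 3)))
    p = float(2.0 * spstats.norm.sf(abs(z)))
    return TopoComparison(r_im_ssvep=r1, r_im_swift=r2, z=z, p=p, n_channels=n)
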