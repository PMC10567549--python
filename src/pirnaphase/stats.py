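"""Between-genotype abundance comparisons and qPCR ΔΔCt with error
propagation."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class AbundanceComparison:
    fold_change: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def compare_abundance(
    control: Sequence[float],
    treatment: Sequence[float],
    exact_threshold: int = 8,
) -> AbundanceComparison:
    """Fold change and two-sided Mann-Whitney p between two groups.

    The fold change is mean(treatment)/mean(control). The exact null
    distribution of U is used when both groups have at most
    ``exact_threshold`` values (typical library group sizes here are 2-3);
    the normal approximation is used above that.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treatment, dtype=float)
    if c.size == 0 or t.size == 0:
        raise ValueError("insufficient_group")
    method = "exact" if max(c.size, t.size) <= exact_threshold else "asymptotic"
    res = sps.mannwhitneyu(t, c, alternative="two-sided", method=method)
    return AbundanceComparison(
        fold_change=float(t.mean() / c.mean()),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate qPCR Ct values for a target and its reference gene."""

    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]
    condition: str = ""

    def delta_ct(self) -> tuple[float, float | None]:
        """ΔCt = mean(target) - mean(reference); σ propagated in quadrature.

        σ is None when either side has fewer than two replicates.
        """
        t = np.asarray(self.ct_target, dtype=float)
        r = np.asarray(self.ct_reference, dtype=float)
        if t.size == 0 or r.size == 0 or not (np.isfinite(t).all() and np.isfinite(r).all()):
            raise ValueError("Ct values must be finite and non-empty")
        dct = float(t.mean() - r.mean())
        if t.size < 2 or r.size < 2:
            return dct, None
        return dct, propagate_sigma(float(t.std(ddof=1)), float(r.std(ddof=1)))


def propagate_sigma(sigma_y: float, sigma_z: float) -> float:
    """Quadrature propagation for a difference: σ = sqrt(σy² + σz²)."""
    return math.sqrt(sigma_y**2 + sigma_z**2)


@dataclass(frozen=True)
class DdctResult:
    fold: float           # 2^(-ΔΔCt)
    ddct: float
    sigma: float | None   # σ of ΔΔCt, None if replicates insufficient


def ddct(measure: CtMeasurement, control: CtMeasurement) -> DdctResult:
    """Relative expression by the 2^(-ΔΔCt) method.

    ΔΔCt = ΔCt(measure) - ΔCt(control); σ values are propagated in
    quadrature at each subtraction. The fold is returned even when too few
    replicates exist to estimate σ.
    """
    dct_m, sig_m = measure.delta_ct()
    dct_c, sig_c = control.delta_ct()
    dd = dct_m - dct_c
    sigma = propagate_sigma(sig_m, sig_c) if (sig_m is not None and sig_c is not None) else None
    return DdctResult(fold=2.0 ** (-dd), ddct=dd, sigma=sigma)
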