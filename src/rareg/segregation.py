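"""Weinberg proband segregation analysis and ascertainment-probability MLE.

Families enter a survey registry through probands — affected persons who
were independently registered.  Under *multiple incomplete ascertainment*
(each affected is a proband independently with registration probability
``pi``), Weinberg's proband method gives an unbiased estimate of the
segregation frequency ``p``:

    p_hat = sum_f b_f (a_f - 1) / sum_f b_f (s_f - 1)

where sibship ``f`` has ``s_f`` children, ``a_f`` affected and ``b_f``
probands: every proband contributes its sibship once with itself removed.
The registration probability is estimated separately by maximum likelihood
on the proband counts, which given the affected counts follow a
zero-truncated binomial law (a family with no proband is never seen):

    P(b | a, ascertained) = C(a, b) pi^b (1 - pi)^(a - b) / (1 - (1 - pi)^a)

Families with a single affected (a = 1) always show b = 1 and carry no
information about ``pi``; they are excluded from the likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .registry import Registry
from .types import Inheritance, Sibship

logger = logging.getLogger(__name__)

#: Mendelian segregation frequency expected for fully penetrant traits.
EXPECTED_SEGREGATION = {Inheritance.AD: 0.5, Inheritance.AR: 0.25, Inheritance.XL: 0.5}


@dataclass(frozen=True)
class SegregationResult:
    """Weinberg proband estimate of the segregation frequency."""

    p_hat: float
    se_p: float
    n_sibships: int
    n_probands: int
    expected_p: Optional[float] = None
    z_statistic: Optional[float] = None
    p_value: Optional[float] = None


@dataclass(frozen=True)
class AscertainmentResult:
    """Zero-truncated-binomial MLE of the registration probability."""

    pi_hat: float
    log_likelihood: float
    n_families: int
    n_excluded_singletons: int
    converged: bool


def _as_arrays(sibships: Union[Sequence[Sibship], pd.DataFrame]) -> Tuple[np.ndarray, ...]:
    """Extract (s, a, b) integer arrays from a sibship list or DataFrame."""
    if isinstance(sibships, pd.DataFrame):
        s = sibships["size_s"].to_numpy(dtype=np.int64)
        a = sibships["affected_a"].to_numpy(dtype=np.int64)
        b = sibships["probands_b"].to_numpy(dtype=np.int64)
    else:
        sibships = list(sibships)
        s = np.array([f.size_s for f in sibships], dtype=np.int64)
        a = np.array([f.affected_a for f in sibships], dtype=np.int64)
        b = np.array([f.probands_b for f in sibships], dtype=np.int64)
    if len(s) == 0:
        raise ValueError("no sibships supplied")
    if np.any((b > a) | (a > s)):
        raise ValueError("invalid sibship: b <= a <= s violated")
    return s, a, b


def weinberg_proband_estimate(
    sibships: Union[Sequence[Sibship], pd.DataFrame],
    expected_p: Optional[float] = None,
) -> SegregationResult:
    """Estimate the segregation frequency by Weinberg's proband method.

    Every sibship must be ascertained (``b >= 1``).  Sibships of size 1
    contribute nothing to either sum (``s - 1 = 0``) but are accepted.
    ``expected_p`` (e.g. 0.25 for AR, 0.5 for AD) enables a two-sided
    z-test of agreement with the Mendelian expectation.

    Raises ``ValueError`` if any sibship has ``b = 0`` (not ascertained)
    or if the denominator is zero (all sibships of size 1).
    """
    s, a, b = _as_arrays(sibships)
    if np.any(b < 1):
        raise ValueError("sibship with b=0 supplied: not ascertained, cannot enter the estimate")
    numerator = float(np.sum(b * (a - 1)))
    denominator = float(np.sum(b * (s - 1)))
    if denominator == 0:
        raise ValueError("estimator undefined: all sibships have size 1 (denominator 0)")
    p_hat = numerator / denominator
    se_p = math.sqrt(p_hat * (1.0 - p_hat) / denominator)
    z = p_value = None
    if expected_p is not None:
        if se_p > 0:
            z = (p_hat - expected_p) / se_p
            p_value = 2.0 * float(stats.norm.sf(abs(z)))
        else:
            z, p_value = math.nan, math.nan
    return SegregationResult(
        p_hat=p_hat,
        se_p=se_p,
        n_sibships=int(len(s)),
        n_probands=int(b.sum()),
        expected_p=expected_p,
        z_statistic=z,
        p_value=p_value,
    )


def truncated_binomial_loglik(
    pi: Union[float, np.ndarray], a: np.ndarray, b: np.ndarray
) -> Union[float, np.ndarray]:
    """Log-likelihood of proband counts under zero-truncated binomial sampling.

    Vectorized over ``pi`` (scalar or array); ``a``/``b`` are per-family
    affected and proband counts with ``1 <= b <= a``.
    """
    pi = np.asarray(pi, dtype=float)
    scalar = pi.ndim == 0
    pi = np.atleast_1d(pi)[:, None]
    choose = special.gammaln(a + 1) - special.gammaln(b + 1) - special.gammaln(a - b + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pi = np.log(pi)
        log_q = np.log1p(-pi)
        # (a - b) * log_q is 0 * -inf when b == a at pi == 1; define it as 0.
        tail = np.where((a - b) == 0, 0.0, (a - b) * log_q)
        terms = choose + b * log_pi + tail - np.log1p(-np.exp(a * log_q))
    total = terms.sum(axis=1)
    return float(total[0]) if scalar else total


def estimate_ascertainment_prob(
    sibships: Union[Sequence[Sibship], pd.DataFrame],
    tol: float = 1e-8,
) -> AscertainmentResult:
    """MLE of the registration probability ``pi`` from proband counts.

    Only families with ``a >= 2`` are informative; single-affected families
    are excluded (their count is reported).  The likelihood is maximized by
    bounded 1-D optimization on ``[1e-6, 1]``; when every informative
    family has ``b = a`` the optimum is the boundary ``pi = 1``.

    Raises ``ValueError`` when no informative family exists: with only
    single-affected families every ascertained family shows b = 1 whatever
    ``pi``, so the registration probability is unidentifiable.
    """
    _, a_all, b_all = _as_arrays(sibships)
    if np.any(a_all < 1) or np.any(b_all < 1):
        raise ValueError("ascertainment MLE needs a >= 1 and b >= 1 in every sibship")
    informative = a_all >= 2
    n_excluded = int(np.sum(~informative))
    a, b = a_all[informative], b_all[informative]
    if len(a) == 0:
        raise ValueError(
            "pi unidentifiable: every family has a single affected (a=1), "
            "whose proband count is 1 for any registration probability"
        )
    if np.all(b == a):
        # Likelihood is increasing in pi up to the boundary.
        return AscertainmentResult(
            pi_hat=1.0,
            log_likelihood=float(truncated_binomial_loglik(1.0 - 1e-12, a, b)),
            n_families=int(len(a)),
            n_excluded_singletons=n_excluded,
            converged=True,
        )
    result = optimize.minimize_scalar(
        lambda pi: -truncated_binomial_loglik(pi, a, b),
        bounds=(1e-6, 1.0 - 1e-12),
        method="bounded",
        options={"xatol": tol},
    )
    pi_hat = float(result.x)
    return AscertainmentResult(
        pi_hat=pi_hat,
        log_likelihood=float(-result.fun),
        n_families=int(len(a)),
        n_excluded_singletons=n_excluded,
        converged=bool(result.success),
    )


@dataclass(frozen=True)
class SegregationReportEntry:
    inheritance: Inheritance
    segregation: SegregationResult
    ascertainment: Optional[AscertainmentResult]


def segregation_report(
    registry_or_sibships: Union[Registry, Sequence[Sibship], pd.DataFrame],
) -> Dict[Inheritance, SegregationReportEntry]:
    """Per-inheritance segregation and ascertainment estimates (AD and AR).

    X-linked sibships are excluded: male-limited segregation in carrier
    sibships does not satisfy the autosomal proband model.  The
    ascertainment entry is ``None`` when ``pi`` is unidentifiable for that
    inheritance class (all single-affected families).
    """
    if isinstance(registry_or_sibships, Registry):
        frame = registry_or_sibships.sibships
    elif isinstance(registry_or_sibships, pd.DataFrame):
        frame = registry_or_sibships
    else:
        frame = pd.DataFrame(
            [
                {
                    "family_id": f.family_id,
                    "size_s": f.size_s,
                    "affected_a": f.affected_a,
                    "probands_b": f.probands_b,
                    "inheritance": f.inheritance.value,
                }
                for f in registry_or_sibships
            ]
        )
    if not len(frame):
        raise ValueError("no sibships available for segregation analysis")

    report: Dict[Inheritance, SegregationReportEntry] = {}
    for inheritance in (Inheritance.AD, Inheritance.AR):
        subset = frame[frame["inheritance"] == inheritance.value]
        if not len(subset):
            continue
        seg = weinberg_proband_estimate(subset, expected_p=EXPECTED_SEGREGATION[inheritance])
        try:
            asc: Optional[AscertainmentResult] = estimate_ascertainment_prob(subset)
        except ValueError as exc:
            logger.info("ascertainment MLE skipped for %s: %s", inheritance.value, exc)
            asc = None
        report[inheritance] = SegregationReportEntry(
            inheritance=inheritance, segregation=seg, ascertainment=asc
        )
    n_xl = int((frame["inheritance"] == Inheritance.XL.value).sum())
    if n_xl:
        logger.info("segregation_report: %d X-linked sibships excluded from analysis", n_xl)
    if not report:
        raise ValueError("no AD or AR sibships available for segregation analysis")
    return report
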