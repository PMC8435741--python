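"""Random isonymy and random inbreeding from surname frequencies.

Surname concordance is a classical proxy for population structure: under
patrilineal surname transmission the probability that two random
individuals share a surname (random isonymy, I) estimates four times the
random component of the inbreeding coefficient, F_r = I / 4
(Crow-Mange construction).
"""

from __future__ import annotations

from typing import Mapping


def _validate(counts: Mapping[str, int]) -> int:
    if not counts:
        raise ValueError("empty surname counts")
    n = 0
    for surname, count in counts.items():
        if count < 1:
            raise ValueError(f"surname {surname!r} has non-positive count {count}")
        n += int(count)
    return n


def random_isonymy(counts: Mapping[str, int], unbiased: bool = False) -> float:
    """Random isonymy I from surname counts.

    The plug-in estimator is ``I = sum_i p_i**2`` with ``p_i`` the sample
    surname frequencies.  With ``unbiased=True`` the without-replacement
    form ``sum_i n_i (n_i - 1) / (n (n - 1))`` is used instead (requires
    at least two individuals).
    """
    n = _validate(counts)
    if unbiased:
        if n < 2:
            raise ValueError("unbiased isonymy needs at least 2 individuals")
        return sum(c * (c - 1) for c in counts.values()) / (n * (n - 1))
    return sum((c / n) ** 2 for c in counts.values())


def random_inbreeding(counts: Mapping[str, int], unbiased: bool = False) -> float:
    """Random component of inbreeding, F_r = I / 4."""
    return random_isonymy(counts, unbiased=unbiased) / 4.0
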