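"""Generalized second-order texture operators over the ring co-occurrence matrix.

Six operators, each a parametric generalization of a Haralick-style
statistic of the joint distribution p_d(i, j):

==================  ==========================================================
homogeneity HG      sum p^n3                  (macrotexture: uniformity)
contrast CT         sum |i-j|^n4 p^n5         (macrotexture: amplitude change)
inverse diff. ID    sum p^n6 / (1+|i-j|^n7)   (microtexture: local repetition)
entropy ET          -sum p^n8 (log_k1 p)^n9   (microtexture: randomness)
correlation CR      sum (i-mu_x)(i-mu_y) p^n10 / (sigma_x sigma_y)^n11
difference ent. DE  -sum_k p_diff(k)^n12 (log_k2 p_diff(k))^n13
==================  ==========================================================

Zero-probability cells contribute nothing to the entropies.  CR is available
both in the printed form (``as_printed``, first factor pair (i-mu_x)(i-mu_y))
and in the conventional Haralick form (``haralick``, (i-mu_x)(j-mu_y)); they
differ on anti-correlated mass.  A constant window has zero marginal
variance, for which CR returns the sentinel 0 with a degenerate flag so that
feature maps stay total functions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cooccurrence import CooccurrenceMatrix, CooccurrenceMarginals

__all__ = ["OperatorSpec", "homogeneity", "contrast", "inverse_difference",
           "entropy", "correlation", "difference_entropy", "OPERATOR_NAMES"]

OPERATOR_NAMES = ("M", "C", "HG", "CT", "ID", "ET", "CR", "DE")

# required exponent parameters (and defaults for bases) per operator family
_PARAM_SCHEMA = {
    "M": {"n1": None},
    "C": {"n2": None},
    "HG": {"n3": None},
    "CT": {"n4": None, "n5": None},
    "ID": {"n6": None, "n7": None},
    "ET": {"n8": None, "n9": None, "k1": 2},
    "CR": {"n10": None, "n11": None},
    "DE": {"n12": None, "n13": None, "k2": 2, "q": 1},
}
_FIRST_ORDER = ("M", "C")


@dataclass(frozen=True)
class OperatorSpec:
    """An operator identity plus its exponent/base/radius parameters.

    Examples
    --------
    >>> OperatorSpec("ET", {"n8": 2, "n9": 3}, d=2).label
    'ET(d=2)(n8=2,n9=3,k1=2)'
    """

    name: str
    params: dict = field(default_factory=dict)
    d: int | None = None
    variant: str = "as_printed"  # CR only: 'as_printed' | 'haralick'

    def __post_init__(self) -> None:
        if self.name not in OPERATOR_NAMES:
            raise ValueError(f"unknown operator {self.name!r}")
        schema = _PARAM_SCHEMA[self.name]
        params = dict(self.params)
        for key, default in schema.items():
            if key not in params:
                if default is None:
                    raise ValueError(f"operator {self.name} requires parameter {key}")
                params[key] = default
        extra = set(params) - set(schema)
        if extra:
            raise ValueError(f"operator {self.name} got unknown parameters {sorted(extra)}")
        for key, val in params.items():
            if int(val) != val or val < 1:
                raise ValueError(f"{key} must be a natural number >= 1, got {val!r}")
            params[key] = int(val)
        if self.name in ("ET",) and params["k1"] < 2:
            raise ValueError("log base k1 must be >= 2")
        if self.name in ("DE",) and params["k2"] < 2:
            raise ValueError("log base k2 must be >= 2")
        if self.name in _FIRST_ORDER:
            if self.d is not None:
                raise ValueError(f"first-order operator {self.name} takes no radius d")
        else:
            if self.d is None or self.d < 1:
                raise ValueError(f"operator {self.name} requires a ring radius d >= 1")
        if self.name == "ID" and params["n7"] % 2 == 1:
            warnings.warn(
                "odd n7: ID denominator uses |i-j|^n7 to avoid zero/negative "
                "denominators", stacklevel=2)
        if self.variant not in ("as_printed", "haralick"):
            raise ValueError("variant must be 'as_printed' or 'haralick'")
        object.__setattr__(self, "params", params)

    @property
    def is_second_order(self) -> bool:
        return self.name not in _FIRST_ORDER

    @property
    def label(self) -> str:
        ps = ",".join(f"{k}={v}" for k, v in self.params.items())
        head = f"{self.name}(d={self.d})" if self.is_second_order else self.name
        tail = f"({ps})" if ps else ""
        var = "" if self.variant == "as_printed" else f"[{self.variant}]"
        return head + tail + var

    def to_dict(self) -> dict:
        return {"name": self.name, "params": dict(self.params), "d": self.d,
                "variant": self.variant}

    @classmethod
    def from_dict(cls, data: dict) -> "OperatorSpec":
        return cls(data["name"], dict(data.get("params", {})), d=data.get("d"),
                   variant=data.get("variant", "as_printed"))


def _sparse(cm: CooccurrenceMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    i, j = np.nonzero(cm.counts)
    p = cm.counts[i, j] / cm.total
    return i.astype(float), j.astype(float), p


def homogeneity(cm: CooccurrenceMatrix, n3: int) -> float:
    """HG(d)(n3) = sum p^n3; high on uniform zones, 1 when n3 = 1."""
    _, _, p = _sparse(cm)
    return float(np.sum(p ** n3))


def contrast(cm: CooccurrenceMatrix, n4: int, n5: int) -> float:
    """CT(d)(n4, n5) = sum |i-j|^n4 p^n5; exactly 0 on constant windows."""
    i, j, p = _sparse(cm)
    return float(np.sum(np.abs(i - j) ** n4 * p ** n5))


def inverse_difference(cm: CooccurrenceMatrix, n6: int, n7: int) -> float:
    """ID(d)(n6, n7) = sum p^n6 / (1 + |i-j|^n7)."""
    i, j, p = _sparse(cm)
    return float(np.sum(p ** n6 / (1.0 + np.abs(i - j) ** n7)))


def entropy(cm: CooccurrenceMatrix, n8: int, n9: int, k1: int = 2) -> float:
    """ET(d)(n8, n9) = -sum p^n8 (log_k1 p)^n9, zero cells contributing 0."""
    _, _, p = _sparse(cm)
    logs = np.log(p) / math.log(k1)
    return float(-np.sum(p ** n8 * logs ** n9))


def correlation(cm: CooccurrenceMatrix, m: CooccurrenceMarginals, n10: int,
                n11: int, variant: str = "as_printed",
                with_flag: bool = False):
    """CR(d)(n10, n11) with selectable numerator convention.

    ``as_printed`` uses (i - mu_x)(i - mu_y); ``haralick`` the conventional
    (i - mu_x)(j - mu_y).  A degenerate (zero-variance) matrix yields the
    sentinel value 0; pass ``with_flag=True`` to receive ``(value, flag)``.
    """
    denom = (m.sigma_x * m.sigma_y) ** n11
    if denom == 0.0:
        return (0.0, True) if with_flag else 0.0
    i, j, p = _sparse(cm)
    second = (i - m.mu_y) if variant == "as_printed" else (j - m.mu_y)
    value = float(np.sum((i - m.mu_x) * second * p ** n10) / denom)
    return (value, False) if with_flag else value


def difference_entropy(m: CooccurrenceMarginals, n12: int, n13: int,
                       k2: int = 2) -> float:
    """DE(d)(n12, n13) = -sum_k p_diff(k)^n12 (log_k2 p_diff(k))^n13."""
    pd = np.asarray(m.p_diff)
    pd = pd[pd > 0]
    logs = np.log(pd) / math.log(k2)
    return float(-np.sum(pd ** n12 * logs ** n13))


def apply_operator(spec: OperatorSpec, cm: CooccurrenceMatrix,
                   m: CooccurrenceMarginals | None = None) -> float:
    """Evaluate any second-order OperatorSpec on a prepared matrix."""
    from .cooccurrence import marginals as _marginals

    if not spec.is_second_order:
        raise ValueError("apply_operator handles second-order operators only")
    ps = spec.params
    if spec.name == "HG":
        return homogeneity(cm, ps["n3"])
    if spec.name == "CT":
        return contrast(cm, ps["n4"], ps["n5"])
    if spec.name == "ID":
        return inverse_difference(cm, ps["n6"], ps["n7"])
    if spec.name == "ET":
        return entropy(cm, ps["n8"], ps["n9"], ps["k1"])
    if m is None:
        m = _marginals(cm, q=ps.get("q", 1))
    if spec.name == "CR":
        return correlation(cm, m, ps["n10"], ps["n11"], spec.variant)
    return difference_entropy(m, ps["n12"], ps["n13"], ps["k2"])
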