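"""Core data containers: time-course measurements and prior edge confidences.

A dynamic Bayesian network (DBN) over ``|V|`` observed variables is learned
from one or more replicate time courses.  Each course is a ``T_m x |V|``
matrix of real measurements; edges run from timepoint ``t-1`` to ``t``.
Prior knowledge enters as a ``|V| x |V|`` matrix of per-edge confidences
``c_ij`` in ``[0, 1]``, entry ``(i, j)`` being the prior belief that ``i``
is a parent of ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeCourseSet", "PriorConfidences"]


@dataclass(frozen=True)
class TimeCourseSet:
    """A collection of replicate time courses over a shared variable set.

    Parameters
    ----------
    variables:
        Ordered variable names; column order of every course.
    courses:
        One ``T_m x |V|`` float array per replicate course, ``T_m >= 2``.
    """

    variables: tuple[str, ...]
    courses: tuple[np.ndarray, ...]

    def __init__(self, variables, courses):
        variables = tuple(str(v) for v in variables)
        if len(set(variables)) != len(variables):
            raise ValueError("duplicate variable names")
        clean = []
        for m, course in enumerate(courses):
            arr = np.asarray(course, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(variables):
                raise ValueError(
                    f"course {m} has shape {arr.shape}; expected (T_m, {len(variables)})"
                )
            if arr.shape[0] < 2:
                raise ValueError(f"course {m} has fewer than 2 timepoints")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"course {m} contains non-finite values")
            clean.append(arr)
        if not clean:
            raise ValueError("at least one time course is required")
        object.__setattr__(self, "variables", variables)
        object.__setattr__(self, "courses", tuple(clean))

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def n_courses(self) -> int:
        return len(self.courses)

    @property
    def n_transitions(self) -> int:
        """Total number of (t-1 -> t) transition rows pooled over courses."""
        return sum(c.shape[0] - 1 for c in self.courses)

    def stacked_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Pooled lagged design: (X_minus, X_plus), each ``n x |V|``.

        Row order is deterministic: courses in input order, time ascending.
        ``X_minus`` holds timepoints ``1..T_m-1`` and ``X_plus`` the matching
        timepoints ``2..T_m``.
        """
        x_minus = np.vstack([c[:-1] for c in self.courses])
        x_plus = np.vstack([c[1:] for c in self.courses])
        return x_minus, x_plus

    def standardize(self) -> "TimeCourseSet":
        """Center and scale each variable's pooled column to unit variance.

        Columns with zero pooled variance are centered only.
        """
        pooled = np.vstack(self.courses)
        mean = pooled.mean(axis=0)
        std = pooled.std(axis=0, ddof=0)
        std = np.where(std > 0, std, 1.0)
        return TimeCourseSet(self.variables, tuple((c - mean) / std for c in self.courses))

    def index_of(self, name: str) -> int:
        try:
            return self.variables.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}") from None


@dataclass(frozen=True)
class PriorConfidences:
    """Per-edge prior confidences ``c_ij`` in [0, 1].

    Entry ``conf[i, j]`` is the prior confidence that variable ``i`` is a
    parent of variable ``j``.  Binary confidences recover the classical
    reference-graph prior; intermediate values interpolate it.
    """

    variables: tuple[str, ...]
    conf: np.ndarray = field(repr=False)

    def __init__(self, variables, conf):
        variables = tuple(str(v) for v in variables)
        arr = np.asarray(conf, dtype=float)
        v = len(variables)
        if arr.shape != (v, v):
            raise ValueError(f"confidence matrix has shape {arr.shape}; expected ({v}, {v})")
        if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
            raise ValueError("confidences must be finite and lie in [0, 1]")
        object.__setattr__(self, "variables", variables)
        object.__setattr__(self, "conf", arr)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def reference_sizes(self) -> np.ndarray:
        """Column sums ``s_hat_j = sum_i c_ij``: the prior-implied typical
        parent-set size of each vertex."""
        return self.conf.sum(axis=0)

    def reorder(self, variables) -> "PriorConfidences":
        """Align to a new variable ordering (by name)."""
        variables = tuple(str(v) for v in variables)
        missing = set(variables) - set(self.variables)
        if missing:
            raise KeyError(f"prior is missing variables: {sorted(missing)}")
        idx = np.array([self.variables.index(v) for v in variables])
        return PriorConfidences(variables, self.conf[np.ix_(idx, idx)])
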