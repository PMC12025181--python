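"""Community stability via the average variation degree (AVD).

For a stratum of k samples and the n functional groups whose values
vary within it, AVD is the mean absolute standardized deviation

    AVD = sum_i sum_j |x_ij - xbar_i| / delta_i / (k * n),

with xbar_i and delta_i the mean and (n-1 denominator) standard
deviation of group i across the stratum's samples. Lower AVD means a
more stable community; 1 - AVD is conventionally plotted as a
stability score. Groups with zero variance carry no information about
variation and are excluded from both the numerator and n (they are
reported). AVD is invariant to per-group rescaling and shifts, and to
sample order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .functional_groups import BiomassMatrix
from .io_core import AbundanceTable, ValidationError

logger = logging.getLogger("phytofg")


@dataclass
class AVDResult:
    """Average variation degree of one stratum."""

    stratum_kind: str            # year | site | custom
    stratum_key: object
    k: int                       # samples in stratum
    n: int                       # groups with nonzero variance
    avd: float
    per_group: dict[str, float]  # group -> mean |standardized deviation|
    zero_variance_groups: list[str] = field(default_factory=list)

    @property
    def stability_score(self) -> float:
        return 1.0 - self.avd


def _matrix_and_labels(data) -> tuple[np.ndarray, list[str], list]:
    if isinstance(data, BiomassMatrix):
        return data.biomass, list(data.groups), list(data.samples)
    if isinstance(data, AbundanceTable):
        return data.abundance, list(data.taxon_ids), list(data.samples)
    X = np.asarray(data, dtype=float)
    return X, [f"g{j}" for j in range(X.shape[1])], list(range(X.shape[0]))


def avd(data, stratum: np.ndarray | list[int] | None = None,
        stratum_kind: str = "custom", stratum_key=None,
        ddof: int = 1) -> AVDResult:
    """Average variation degree over a set of samples.

    ``data`` is a BiomassMatrix (default analysis level), an
    AbundanceTable (species-level variant) or a plain samples-by-groups
    array. ``stratum`` selects rows (indices or boolean mask; default
    all). ``ddof=1`` gives the sample standard deviation; ``ddof=0``
    the population variant.
    """
    X, labels, _ = _matrix_and_labels(data)
    if stratum is not None:
        stratum = np.asarray(stratum)
        X = X[stratum] if stratum.dtype != bool else X[np.flatnonzero(stratum)]
    k = X.shape[0]
    if k < 2:
        raise ValidationError(f"stratum has k={k} samples; need >= 2")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    # a numerically constant column yields sd ~ 1e-16 * |mean| from mean
    # rounding; treat it as zero-variance
    variable = sd > 1e-12 * np.abs(mean)
    zero_var = [labels[j] for j in np.flatnonzero(~variable)]
    n = int(variable.sum())
    if n == 0:
        raise ValidationError("all groups have zero variance in stratum")
    if zero_var:
        logger.info("excluding %d zero-variance group(s): %s",
                    len(zero_var), zero_var)
    Z = np.abs(X[:, variable] - mean[variable]) / sd[variable]
    value = float(Z.sum() / (k * n))
    per_group = {labels[j]: float(np.abs(X[:, j] - mean[j]).mean() / sd[j])
                 for j in np.flatnonzero(variable)}
    return AVDResult(stratum_kind=stratum_kind, stratum_key=stratum_key,
                     k=k, n=n, avd=value, per_group=per_group,
                     zero_variance_groups=zero_var)


def avd_by(data, by: str = "year", ddof: int = 1) -> list[AVDResult]:
    """One AVDResult per year (pooling sites) or per site (pooling dates).

    Strata that fail the preconditions (too few samples, no variable
    groups) are reported and skipped; the rest are still returned.
    """
    if by not in ("year", "site"):
        raise ValidationError(f"unknown stratification {by!r}")
    _, _, samples = _matrix_and_labels(data)
    if not samples or not isinstance(samples[0], tuple):
        raise ValidationError("avd_by needs sample (site, date) keys")
    keys = sorted({s[1].year if by == "year" else s[0] for s in samples})
    results = []
    for key in keys:
        if by == "year":
            mask = np.array([d.year == key for _, d in samples])
        else:
            mask = np.array([s == key for s, _ in samples])
        try:
            results.append(avd(data, stratum=mask, stratum_kind=by,
                               stratum_key=key, ddof=ddof))
        except ValidationError as exc:
            logger.warning("stratum %s=%r skipped: %s", by, key, exc)
    return results
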