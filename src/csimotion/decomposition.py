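"""Stage 2: SVD-based principal component selection.

Of the 180 filtered subcarrier columns only some respond to the target
motion; PCA concentrates the coherent motion response into a few components.
The columns of the filtered matrix A are mean-centered and decomposed as
A = U S V^T; each candidate time series is the projection score A v_k
(length T), and the one with the largest variance — the leading component —
is selected, sign-fixed so its crests point upward, and z-score renormalized
for the segmentation stage.

In multi-link mode the subcarrier columns of all links are concatenated
before a single decomposition, so one component summarizes every link.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocessing import NormalizedSequence

logger = logging.getLogger(__name__)


@dataclass
class ComponentSelection:
    """Selected motion component and decomposition diagnostics.

    component_series is the selected projection score, renormalized to zero
    mean and unit (population) standard deviation; explained_variation holds
    the per-component variance of each projection score.
    """

    component_series: np.ndarray
    component_index: int
    singular_values: np.ndarray
    explained_variation: np.ndarray

    @property
    def n_times(self) -> int:
        return self.component_series.size


def select_principal_component(A: NormalizedSequence | np.ndarray) -> ComponentSelection:
    """Pick the maximal-variance principal component time series of A.

    Zero-variance columns (e.g. subcarriers nulled by filtering) are dropped
    with a warning before the decomposition.  The SVD's sign ambiguity is
    resolved by flipping the selected series so its sample skewness is
    nonnegative (peaks point up, as the peak finder downstream assumes).
    """
    values = A.values if isinstance(A, NormalizedSequence) else np.asarray(A, float)
    if values.ndim == 1:
        values = values[:, None]
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix contains non-finite entries")
    if np.all(values == 0):
        raise ValueError("all-zero matrix: no signal to decompose")

    sd = values.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        logger.warning(
            "select_principal_component: dropping %d zero-variance column(s)",
            int((~keep).sum()),
        )
        values = values[:, keep]

    T = values.shape[0]
    centered = values - values.mean(axis=0)
    # economy SVD: scores = U S are the projections A v_k
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    explained = s**2 / T  # population variance of each centered score
    index = int(np.argmax(explained))
    series = scores[:, index]

    skew = np.mean(series**3)  # unit-scale proxy; only the sign matters
    if skew < 0:
        series = -series

    sd_sel = series.std()
    if sd_sel == 0:
        raise ValueError("selected component is constant; no signal to normalize")
    series = (series - series.mean()) / sd_sel

    logger.debug(
        "select_principal_component: index=%d singular_values=%s",
        index,
        np.array2string(s[: min(6, s.size)], precision=3),
    )
    return ComponentSelection(
        component_series=series,
        component_index=index,
        singular_values=s,
        explained_variation=explained,
    )


def concatenate_links(links: list[NormalizedSequence]) -> NormalizedSequence:
    """Multi-link mode: stack the subcarrier columns of several links so one
    SVD processes them together."""
    if not links:
        raise ValueError("no links given")
    fs = links[0].fs
    T = links[0].values.shape[0]
    for link in links[1:]:
        if link.values.shape[0] != T or link.fs != fs:
            raise ValueError("links must share length and sampling rate")
    return NormalizedSequence(
        np.hstack([link.values for link in links]), fs=fs, stage=links[0].stage
    )
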