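"""Latent-structure specifications (loadings, factor covariance, residuals).

A :class:`ModelSpec` encodes a confirmatory model as patterns over the
loading matrix Lambda (indicators x latents), the factor covariance Phi
(latents x latents), and the residual variances Theta (diagonal).  In every
pattern ``nan`` marks a free parameter and a number a fixed value.  All
models use unit-variance identification: latent variances are fixed to 1
(including the optional second-order factor), so free off-diagonal Phi
entries are correlations and standardized solutions are directly
comparable across the model zoo.

The zoo covers the structures commonly pitted against each other for
co-occurring symptom domains (here eating-disorder symptom scores AN/BN/BED
and three suicidal-ideation items TAF1-3):

``two_factor``
    Two correlated first-order factors (ED, SI).
``hierarchical``
    The two first-order factors load on a second-order general
    susceptibility factor.  With only two first-order factors the
    second-order loadings are constrained equal for identification.
``residual``
    A bifactor model: one general susceptibility factor over all six
    indicators plus two specific (residual) factors, all mutually
    orthogonal.
``four_factor``
    Four correlated first-order factors (restricting, purging, bingeing,
    suicidal ideation); the three single-indicator factors are identified
    by fixing their residual variances to zero.

Each structure exists with and without depression/anxiety sum scores
(PHQ8, GAD7): ``replace_general`` loads them on the general/susceptibility
side, ``separate_factor`` gives them their own factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelSpec", "SecondOrder", "make_model_spec"]

ED = ["AN_score", "BN_score", "BED_score"]
TAF = ["TAF1", "TAF2", "TAF3"]
PSY = ["PHQ8", "GAD7"]

FREE = np.nan


@dataclass
class SecondOrder:
    """Second-order layer: first-order factors load on higher-order factors.

    ``loadings`` is a (k1, k2) pattern (nan free / value fixed).  The
    second-order factor variances are fixed to 1 and each first-order
    disturbance is implied as 1 - (row sum of squared loadings), keeping
    unit first-order variances.  ``equal_loadings`` ties all free loadings
    to a single parameter (required for identification with two first-order
    factors).
    """

    loadings: np.ndarray
    equal_loadings: bool = False
    names: list[str] = field(default_factory=lambda: ["general"])


@dataclass
class ModelSpec:
    indicators: list[str]
    latents: list[str]
    loadings: np.ndarray  # p x k pattern
    factor_cov: np.ndarray  # k x k pattern; diagonal must be fixed (unit variance)
    residual_var: np.ndarray  # length-p pattern
    second_order: SecondOrder | None = None
    loading_ties: list[list[tuple[int, int]]] = field(default_factory=list)
    structure: str = "custom"
    variant: str = "none"

    def __post_init__(self) -> None:
        p, k = len(self.indicators), len(self.latents)
        self.loadings = np.asarray(self.loadings, dtype=np.float64).reshape(p, k)
        self.factor_cov = np.asarray(self.factor_cov, dtype=np.float64).reshape(k, k)
        self.residual_var = np.asarray(self.residual_var, dtype=np.float64).reshape(p)
        if np.isnan(np.diag(self.factor_cov)).any():
            raise ValueError(
                "latent variances must be fixed (unit-variance identification)"
            )
        for j in range(k):
            col = self.loadings[:, j]
            if not (np.isnan(col).any() or (col[~np.isnan(col)] != 0).any()):
                raise ValueError(
                    f"latent {self.latents[j]!r} has no free or fixed-nonzero loading"
                )
        if self.second_order is not None:
            off = ~np.eye(k, dtype=bool)
            if np.isnan(self.factor_cov[off]).any():
                raise ValueError(
                    "factor covariances must be fixed when a second-order layer "
                    "generates them"
                )

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    @property
    def n_latents(self) -> int:
        return len(self.latents)

    def free_param_count(self, include_means: bool = True) -> int:
        """Number of free parameters, honouring ties."""
        p, k = self.n_indicators, self.n_latents
        tied = {pos for group in self.loading_ties for pos in group}
        n_lam = int(np.isnan(self.loadings).sum()) - sum(
            len(g) - 1 for g in self.loading_ties
        )
        n_phi = int(np.isnan(self.factor_cov[np.tril_indices(k, -1)]).sum())
        n_th = int(np.isnan(self.residual_var).sum())
        n_so = 0
        if self.second_order is not None:
            n_free_so = int(np.isnan(self.second_order.loadings).sum())
            n_so = 1 if (self.second_order.equal_loadings and n_free_so) else n_free_so
        n_mu = p if include_means else 0
        return n_lam + n_phi + n_th + n_so + n_mu

    def degrees_of_freedom(self) -> int:
        """Model df against the saturated mean/covariance structure."""
        p = self.n_indicators
        return p * (p + 3) // 2 - self.free_param_count(include_means=True)


def _base_patterns(indicators, latents, loading_map):
    p, k = len(indicators), len(latents)
    lam = np.zeros((p, k))
    for lat, inds in loading_map.items():
        j = latents.index(lat)
        for name in inds:
            lam[indicators.index(name), j] = FREE
    phi = np.eye(k)
    theta = np.full(p, FREE)
    return lam, phi, theta


def make_model_spec(
    structure: str,
    with_psychopathology: str = "none",
    constrain_specific_loadings: bool = False,
) -> ModelSpec:
    """Build one of the theoretical models (optionally with PHQ8/GAD7).

    Parameters
    ----------
    structure : {"efa_two_factor", "two_factor", "hierarchical", "residual", "four_factor"}
    with_psychopathology : {"none", "replace_general", "separate_factor"}
    constrain_specific_loadings : bool
        Optional equality constraint on each specific factor's loadings in
        the bifactor ("residual") model; three-indicator specific factors
        can be empirically under-identified, and non-convergence is
        reported rather than silently repaired.
    """
    if structure == "efa_two_factor":
        structure = "two_factor"
    if with_psychopathology not in ("none", "replace_general", "separate_factor"):
        raise ValueError(f"unknown psychopathology variant {with_psychopathology!r}")
    psy = with_psychopathology
    indicators = ED + TAF + (PSY if psy != "none" else [])

    if structure == "two_factor":
        latents = ["ED", "SI"]
        loading_map = {"ED": list(ED), "SI": list(TAF)}
        if psy == "replace_general":
            loading_map["SI"] = TAF + PSY
        elif psy == "separate_factor":
            latents = latents + ["PSY"]
            loading_map["PSY"] = list(PSY)
        lam, phi, theta = _base_patterns(indicators, latents, loading_map)
        k = len(latents)
        phi[np.tril_indices(k, -1)] = FREE
        phi[np.triu_indices(k, 1)] = FREE
        return ModelSpec(indicators, latents, lam, phi, theta, structure="two_factor", variant=psy)

    if structure == "hierarchical":
        latents = ["ED", "SI"]
        loading_map = {"ED": list(ED), "SI": list(TAF)}
        if psy == "replace_general":
            loading_map["SI"] = TAF + PSY
        elif psy == "separate_factor":
            latents = latents + ["PSY"]
            loading_map["PSY"] = list(PSY)
        lam, phi, theta = _base_patterns(indicators, latents, loading_map)
        k = len(latents)
        so = SecondOrder(
            loadings=np.full((k, 1), FREE),
            equal_loadings=(k == 2),
            names=["susceptibility"],
        )
        return ModelSpec(
            indicators, latents, lam, phi, theta,
            second_order=so, structure="hierarchical", variant=psy,
        )

    if structure == "residual":
        latents = ["general", "ED_specific", "SI_specific"]
        loading_map = {
            "general": list(indicators),
            "ED_specific": list(ED),
            "SI_specific": list(TAF),
        }
        ties: list[list[tuple[int, int]]] = []
        if psy == "replace_general":
            pass  # PHQ8/GAD7 index the general factor only
        elif psy == "separate_factor":
            latents = latents + ["PSY_specific"]
            loading_map["PSY_specific"] = list(PSY)
        lam, phi, theta = _base_patterns(indicators, latents, loading_map)
        if psy == "separate_factor":
            # two-indicator orthogonal specific: tie its loadings for identification
            j = latents.index("PSY_specific")
            ties.append([(indicators.index(name), j) for name in PSY])
        if constrain_specific_loadings:
            for lat in ("ED_specific", "SI_specific"):
                j = latents.index(lat)
                ties.append(
                    [(i, j) for i in range(len(indicators)) if np.isnan(lam[i, j])]
                )
        return ModelSpec(
            indicators, latents, lam, phi, theta,
            loading_ties=ties, structure="residual", variant=psy,
        )

    if structure == "four_factor":
        latents = ["restricting", "purging", "bingeing", "SI"]
        loading_map = {
            "restricting": ["AN_score"],
            "purging": ["BN_score"],
            "bingeing": ["BED_score"],
            "SI": list(TAF),
        }
        if psy == "replace_general":
            loading_map["SI"] = TAF + PSY
        elif psy == "separate_factor":
            latents = latents + ["PSY"]
            loading_map["PSY"] = list(PSY)
        lam, phi, theta = _base_patterns(indicators, latents, loading_map)
        k = len(latents)
        phi[np.tril_indices(k, -1)] = FREE
        phi[np.triu_indices(k, 1)] = FREE
        # single-indicator factors: residual fixed to 0 (factor == indicator)
        for name in ("AN_score", "BN_score", "BED_score"):
            theta[indicators.index(name)] = 0.0
        return ModelSpec(indicators, latents, lam, phi, theta, structure="four_factor", variant=psy)

    raise ValueError(f"unknown structure {structure!r}")
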