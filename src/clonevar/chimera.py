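"""Periclinal-chimera layer inference from a somatic allele's VAF.

Leaves of a layered meristem chimera mix cells from the L1 (epidermis),
L2 (mesophyll and parenchyma) and L3 (vascular system) lineages.  A
somatic allele on one of the four homologous chromosomes of an
autotetraploid has expected VAF 0.25 only when present in every cell;
when confined to a subset of layers, the expected VAF shrinks to the
mutant cell fraction times copies/ploidy.  Given variant and informative
read counts, the layer pattern is inferred by comparing binomial
likelihoods at each candidate pattern's expected VAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .simdata import DEFAULT_LAYER_FRACTIONS, LAYERS


@dataclass
class LayerModel:
    """Leaf layer cell fractions and the mutant allele's copy number."""

    layer_fractions: tuple[float, float, float] = DEFAULT_LAYER_FRACTIONS
    ploidy: int = 4
    mutant_copies: int = 1  # simplex by default

    def __post_init__(self) -> None:
        if abs(sum(self.layer_fractions) - 1.0) > 1e-9:
            raise ValueError("layer fractions must sum to 1")
        if not 1 <= self.mutant_copies <= self.ploidy:
            raise ValueError("need ploidy >= mutant_copies >= 1")

    def fraction(self, layer: str) -> float:
        return self.layer_fractions[LAYERS.index(layer)]


#: Default candidate layer patterns.  {L2} and {L3} alone are excluded
#: because layer invasion tends to homogenise L2 and L3, so a mutation in
#: either is expected to be observed in both.
DEFAULT_PATTERNS: tuple[frozenset[str], ...] = (
    frozenset({"L1"}),
    frozenset({"L2", "L3"}),
    frozenset({"L1", "L2", "L3"}),
)


def expected_vaf(pattern: Iterable[str], model: LayerModel) -> float:
    """Expected VAF of an allele confined to ``pattern`` layers.

    (sum of layer cell fractions over the pattern) × copies / ploidy;
    0.25 for a simplex allele present in all three layers.  The empty
    pattern gives 0.
    """
    pattern = frozenset(pattern)
    if not pattern <= set(LAYERS):
        raise ValueError(f"pattern must be a subset of {LAYERS}")
    cell_frac = sum(model.fraction(layer) for layer in pattern)
    return cell_frac * model.mutant_copies / model.ploidy


@dataclass
class PatternLikelihood:
    pattern: frozenset[str]
    expected_vaf: float
    log_likelihood: float


@dataclass
class LayerCall:
    """Ranked layer patterns for an observed k-of-n variant count."""

    k: int
    n: int
    candidates: list[PatternLikelihood]  # sorted, best first
    tied: bool
    lr_threshold: float = 10.0

    @property
    def best(self) -> frozenset[str] | None:
        """Best pattern, or ``None`` when the top likelihoods are tied."""
        return None if self.tied else self.candidates[0].pattern

    @property
    def likelihood_ratio(self) -> float:
        """Likelihood ratio of the best pattern over the runner-up."""
        return float(np.exp(self.candidates[0].log_likelihood
                            - self.candidates[1].log_likelihood))

    @property
    def confident(self) -> bool:
        return not self.tied and self.likelihood_ratio >= self.lr_threshold

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "vaf": self.k / self.n,
            "best_pattern": sorted(self.best) if self.best else None,
            "tied": self.tied,
            "likelihood_ratio": self.likelihood_ratio,
            "confident": self.confident,
            "candidates": [
                {
                    "pattern": sorted(c.pattern),
                    "expected_vaf": c.expected_vaf,
                    "log_likelihood": c.log_likelihood,
                }
                for c in self.candidates
            ],
        }


def infer_layer(
    k: int,
    n: int,
    model: LayerModel | None = None,
    patterns: Sequence[Iterable[str]] | None = None,
    lr_threshold: float = 10.0,
) -> LayerCall:
    """Rank candidate layer patterns by binomial likelihood of k of n.

    Patterns whose expected VAFs coincide (within 1e-12) and share the
    top likelihood are reported as tied rather than arbitrarily ranked.
    """
    if not (0 <= k <= n and n > 0):
        raise ValueError("need 0 <= k <= n, n > 0")
    model = model or LayerModel()
    pats = [frozenset(p) for p in (patterns or DEFAULT_PATTERNS)]
    if len(pats) < 2:
        raise ValueError("need at least two candidate patterns")
    cands = []
    for pat in pats:
        ev = expected_vaf(pat, model)
        ll = float(stats.binom.logpmf(k, n, ev)) if 0 < ev < 1 else (
            # degenerate expected VAF of exactly 0 or 1
            0.0 if (ev == 0.0 and k == 0) or (ev == 1.0 and k == n)
            else -np.inf
        )
        cands.append(PatternLikelihood(pat, ev, ll))
    cands.sort(key=lambda c: -c.log_likelihood)
    tied = (len(cands) > 1
            and abs(cands[0].log_likelihood - cands[1].log_likelihood) < 1e-12
            and abs(cands[0].expected_vaf - cands[1].expected_vaf) < 1e-12)
    return LayerCall(k, n, cands, tied, lr_threshold)
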