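"""Trio Mendelian inference of allelic LILRB3/LILRA6 copy-number types.

Diploid CN genotypes do not identify which copies travel together on one
chromosome. With a father/mother/child trio the space of explanations
shrinks sharply: every parental diplotype pair must transmit one haplotype
each whose component-wise sum is the child's genotype. This module
enumerates all parental diplotype configurations over a haplotype space,
scores each by

    f(h_f1) f(h_f2) f(h_m1) f(h_m2) x 1/4
        x P(obs_child | transmitted sum)
        x P(obs_f | father diplotype sum) x P(obs_m | mother diplotype sum)

and returns the MAP configuration plus the full posterior ranking. With
integer genotype inputs the observation terms are equality indicators; with
continuous normalized-CN observations they are Gaussian likelihoods under a
fitted :class:`~lilrcnv.caller.LatticeMixtureCaller` noise model.

The flagship use: a child called (1, 1) with a (1, 1) father and (2, 2)
mother is explained by the father transmitting the hybrid B3:0-A6:0
haplotype -- the signature by which the fusion gene is traced through a
pedigree without long reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .caller import (
    CNGenotype,
    Diplotype,
    HaplotypeCNType,
    LatticeMixtureCaller,
    default_hap_freqs,
    hap_space,
)
from .depth import NormalizedCN
from .errors import InconsistentTrioError, LilrError

__all__ = ["TrioObservation", "TrioConfig", "TrioResult", "enumerate_parent_configs", "trio_map"]

Observation = Union[CNGenotype, NormalizedCN, Tuple[int, int]]


@dataclass(frozen=True)
class TrioObservation:
    father: Observation
    mother: Observation
    child: Observation


@dataclass(frozen=True)
class TrioConfig:
    """One parental explanation: two diplotypes plus the transmitted picks."""

    father: Diplotype
    mother: Diplotype
    transmitted_paternal: HaplotypeCNType
    transmitted_maternal: HaplotypeCNType
    posterior: float = 0.0

    @property
    def child_genotype(self) -> Tuple[int, int]:
        t1, t2 = self.transmitted_paternal, self.transmitted_maternal
        return (t1.h_b3 + t2.h_b3, t1.h_a6 + t2.h_a6)

    def sort_key(self) -> Tuple:
        return (
            -self.posterior,
            self.father.label,
            self.mother.label,
            self.transmitted_paternal.label,
            self.transmitted_maternal.label,
        )


@dataclass
class TrioResult:
    father_diplotype: Diplotype
    mother_diplotype: Diplotype
    transmitted_paternal: HaplotypeCNType
    transmitted_maternal: HaplotypeCNType
    posterior: float
    all_configs: List[TrioConfig] = field(default_factory=list)


def _diplotypes(genotype: Tuple[int, int], space: Sequence[HaplotypeCNType]) -> List[Diplotype]:
    pool = set(space)
    seen = set()
    out = []
    for h1 in space:
        b2, a2 = genotype[0] - h1.h_b3, genotype[1] - h1.h_a6
        if b2 < 0 or a2 < 0:
            continue
        h2 = HaplotypeCNType(b2, a2)
        if h2 not in pool:
            continue
        key = tuple(sorted([h1, h2]))
        if key not in seen:
            seen.add(key)
            out.append(Diplotype(*key))
    return out


def enumerate_parent_configs(
    g_father: Tuple[int, int],
    g_mother: Tuple[int, int],
    space: Optional[Sequence[HaplotypeCNType]] = None,
) -> List[TrioConfig]:
    """All (father diplotype, mother diplotype, paternal pick, maternal pick).

    Complete by construction: every unordered diplotype consistent with each
    parent, crossed with every transmissible member. No child filter is
    applied here.
    """
    space = list(space) if space is not None else hap_space()
    gf = _genotype_tuple(g_father)
    gm = _genotype_tuple(g_mother)
    configs = []
    for df in _diplotypes(gf, space):
        for dm in _diplotypes(gm, space):
            for tf in {df.h1, df.h2}:
                for tm in {dm.h1, dm.h2}:
                    configs.append(TrioConfig(df, dm, tf, tm))
    return configs


def _genotype_tuple(obs) -> Tuple[int, int]:
    if isinstance(obs, CNGenotype):
        return (obs.cn_b3, obs.cn_a6)
    if isinstance(obs, NormalizedCN):
        raise LilrError("continuous observation where an integer genotype is required")
    return (int(obs[0]), int(obs[1]))


def _obs_loglik(obs, genotype: Tuple[int, int], model: Optional[LatticeMixtureCaller]) -> float:
    """log P(observation | integer genotype): indicator or Gaussian."""
    if isinstance(obs, NormalizedCN):
        if model is None:
            raise LilrError(
                "continuous trio observations need a fitted LatticeMixtureCaller "
                "for the observation likelihood"
            )
        return model.observation_loglik(obs.as_array(), genotype)
    g = _genotype_tuple(obs)
    return 0.0 if g == genotype else -np.inf


def trio_map(
    obs: TrioObservation,
    freqs: Optional[Dict[HaplotypeCNType, float]] = None,
    model: Optional[LatticeMixtureCaller] = None,
    space: Optional[Sequence[HaplotypeCNType]] = None,
    uniform_prior: bool = False,
) -> TrioResult:
    """MAP Mendelian configuration for a father/mother/child trio.

    `freqs` supplies the population prior on haplotypes (default: the
    built-in table; `uniform_prior=True` flattens it). Raises
    :class:`InconsistentTrioError` when no configuration has positive
    probability -- a de-novo CNV or genotyping-error signal.
    """
    freqs = dict(freqs) if freqs is not None else default_hap_freqs(space)
    if space is None:
        space = sorted(freqs)
    if uniform_prior:
        freqs = {h: 1.0 for h in space}

    def logf(h: HaplotypeCNType) -> float:
        f = freqs.get(h, 0.0)
        return float(np.log(f)) if f > 0 else -np.inf

    # candidate parental genotypes: fixed for integer observations, the
    # whole lattice reachable from the hap space for continuous ones
    scored: List[TrioConfig] = []
    log_scores: List[float] = []
    if isinstance(obs.father, NormalizedCN) or isinstance(obs.mother, NormalizedCN):
        father_gts = mother_gts = None  # enumerate over all diplotypes
    else:
        father_gts = [_genotype_tuple(obs.father)]
        mother_gts = [_genotype_tuple(obs.mother)]

    if father_gts is None:
        dfs = _all_diplotypes(space)
        dms = dfs
    else:
        dfs = [d for g in father_gts for d in _diplotypes(g, space)]
        dms = [d for g in mother_gts for d in _diplotypes(g, space)]

    for df in dfs:
        lf = logf(df.h1) + logf(df.h2) + _obs_loglik(obs.father, df.genotype(), model)
        if lf == -np.inf:
            continue
        for dm in dms:
            lm = logf(dm.h1) + logf(dm.h2) + _obs_loglik(obs.mother, dm.genotype(), model)
            if lm == -np.inf:
                continue
            for tf in {df.h1, df.h2}:
                for tm in {dm.h1, dm.h2}:
                    child = (tf.h_b3 + tm.h_b3, tf.h_a6 + tm.h_a6)
                    lc = _obs_loglik(obs.child, child, model)
                    score = lf + lm + lc + np.log(0.25)
                    if score == -np.inf:
                        continue
                    scored.append(TrioConfig(df, dm, tf, tm))
                    log_scores.append(score)

    if not scored:
        raise InconsistentTrioError(
            "inconsistent trio: no Mendelian-consistent parental configuration "
            "(possible de-novo CNV or genotyping error)"
        )

    log_scores_arr = np.array(log_scores)
    post = np.exp(log_scores_arr - log_scores_arr.max())
    post /= post.sum()
    ranked = [
        TrioConfig(c.father, c.mother, c.transmitted_paternal, c.transmitted_maternal, float(p))
        for c, p in zip(scored, post)
    ]
    ranked.sort(key=TrioConfig.sort_key)
    best = ranked[0]
    return TrioResult(
        father_diplotype=best.father,
        mother_diplotype=best.mother,
        transmitted_paternal=best.transmitted_paternal,
        transmitted_maternal=best.transmitted_maternal,
        posterior=best.posterior,
        all_configs=ranked,
    )


def _all_diplotypes(space: Sequence[HaplotypeCNType]) -> List[Diplotype]:
    out = []
    seen = set()
    for h1 in space:
        for h2 in space:
            key = tuple(sorted([h1, h2]))
            if key not in seen:
                seen.add(key)
                out.append(Diplotype(*key))
    return out
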