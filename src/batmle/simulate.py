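"""Simulated-night study design for probing the presence test.

The design crosses every species with a ladder of its own file count
and a ladder of the other species' counts. For each target species
there are 25 subsets; subset ``k`` holds ``t = 26 - k`` target files.
Each subset spawns 25 nights; night ``m`` holds ``o = 26 - m`` files of
*each* of the 8 other species. That gives 9 x 25 x 25 = 5,625 nights,
and with a presence p-value computed for each of the 9 species on each
night, 50,625 examined-species records. Every species is truly present
on every night (all counts >= 1), so a significant p-value is a true
positive and a non-significant one a false negative.

Over the whole design the per-night species ratios average exactly 1/9
(~0.11) with a spread of ~0.05, i.e. the design mostly probes low
species ratios — the regime where presence testing is hard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import ConfusionMatrix
from .presence import pvalues_matrix
from .species import CODES, species_index

N_SUBSETS = 25
N_NIGHTS_PER_SUBSET = 25
MAX_COUNT = 25


@dataclass(frozen=True)
class NightDesign:
    """One simulated night: a target species' count ladder position."""

    target: str
    subset_index: int  # 1..25; target count t = 26 - subset_index
    night_index: int  # 1..25; each other species' count o = 26 - night_index

    @property
    def t(self) -> int:
        return 26 - self.subset_index

    @property
    def o(self) -> int:
        return 26 - self.night_index

    @property
    def total(self) -> int:
        return self.t + 8 * self.o

    def counts(self, species: tuple[str, ...] = CODES) -> np.ndarray:
        c = np.full(len(species), float(self.o))
        c[species_index(self.target, species)] = float(self.t)
        return c

    def ratios(self, species: tuple[str, ...] = CODES) -> np.ndarray:
        c = self.counts(species)
        return c / c.sum()


def build_design(species: tuple[str, ...] = CODES) -> list[NightDesign]:
    """The full 9 x 25 x 25 = 5,625-night design, in deterministic order."""
    return [
        NightDesign(target=sp, subset_index=k, night_index=m)
        for sp in species
        for k in range(1, N_SUBSETS + 1)
        for m in range(1, N_NIGHTS_PER_SUBSET + 1)
    ]


def design_counts(design: list[NightDesign], species: tuple[str, ...] = CODES) -> np.ndarray:
    """(N, 9) matrix of true per-species counts for the design nights."""
    return np.array([d.counts(species) for d in design])


def design_summary(design: list[NightDesign], species: tuple[str, ...] = CODES) -> dict:
    """Descriptive statistics of the design's species ratios.

    Returns the mean and population standard deviation over all
    species-night ratios, plus a per-(species, count) tally of how many
    nights place that many files of that species (225 each on the full
    design: 25 as target plus 8 x 25 as an other species).
    """
    ratios = np.array([d.ratios(species) for d in design])  # (N, 9)
    counts = design_counts(design, species).astype(int)
    tallies = (
        pd.DataFrame(counts, columns=list(species))
        .melt(var_name="species", value_name="count")
        .groupby(["species", "count"])
        .size()
        .rename("n_nights")
        .reset_index()
    )
    return {
        "n_nights": len(design),
        "n_records": ratios.size,
        "mean_ratio": float(ratios.mean()),
        "sd_ratio": float(ratios.std()),  # population SD over all records
        "per_count_obs": tallies,
    }


def run_simulation(
    design: list[NightDesign],
    cm: ConfusionMatrix,
    mode: str = "exact",
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run every design night through the presence test.

    Returns a tidy frame with one row per (night, examined species):
    the night's coordinates, the examined species' true count and
    species ratio, its presence p-value, and the TP/FN outcome at
    ``alpha`` (TP because every species is truly present by design).

    ``mode`` controls how the design counts become classified counts:

    - ``exact`` (default): classified counts equal the true counts.
      This emulates the study protocol of building nights only from
      files the classifier is known to identify correctly — the test
      still accounts for the classifier's misclassification rates, so
      it isolates the presence *test* from identification errors.
    - ``expected``: deterministic expectation of the confusion matrix
      applied to the true counts (includes misclassification inflow
      and NOID losses).
    - ``sampled``: each file's assigned label drawn from its species'
      confusion-matrix row with a seeded RNG.
    """
    species = cm.species
    k = len(species)
    C_true = design_counts(design, species)
    if mode == "exact":
        C_class = C_true.copy()
    elif mode == "expected":
        C_class = C_true @ cm.theta[:, :k]
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        C_class = np.zeros_like(C_true)
        for i in range(k):
            draws = rng.multinomial(C_true[:, i].astype(int), cm.theta[i])
            C_class += draws[:, :k]
    else:
        raise ValueError(
            f"mode must be 'exact', 'expected' or 'sampled', got {mode!r}"
        )

    pvals, lam = pvalues_matrix(C_class, cm)

    n = len(design)
    target = np.repeat([d.target for d in design], k)
    rows = pd.DataFrame(
        {
            "target": target,
            "subset": np.repeat([d.subset_index for d in design], k),
            "night": np.repeat([d.night_index for d in design], k),
            "examined": np.tile(list(species), n),
            "count": C_true.ravel(),
            "ratio": (C_true / C_true.sum(axis=1, keepdims=True)).ravel(),
            "total_files": np.repeat(C_true.sum(axis=1), k),
            "pvalue": pvals.ravel(),
            "lr_stat": lam.ravel(),
        }
    )
    rows["outcome"] = np.where(rows["pvalue"] <= alpha, "TP", "FN")
    return rows
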