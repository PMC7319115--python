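"""Posterior-slope quantification of senescence.

For every retained posterior draw, the age-class-specific demographic rate
(survival or breeding success) is evaluated at a reference level of the random
effects and regressed linearly on age; the collection of per-draw OLS slopes
is the posterior distribution of the senescence slope.  Its mean, central 95%
credible interval and the posterior probability that the slope is negative —
p(slope < 0), the evidence measure for senescence — are reported per sex.

Rates are evaluated on the probability scale by default (a slope of -0.05
means the annual rate drops by five percentage points per age class); the
logit scale is available.  The reference is the population average
(population random effect 0) with the individual effect at 0; a named
population reproduces that population's trajectory instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["SlopeSummary", "age_trajectory", "slope_distribution", "table_of_slopes",
           "plot_age_trajectory"]


@dataclass
class SlopeSummary:
    """Posterior distribution of a senescence slope."""

    slope_draws: np.ndarray
    mean: float
    cri_low: float
    cri_high: float
    p_negative: float
    scale: str

    @property
    def p_positive(self) -> float:
        return 1.0 - self.p_negative

    def __repr__(self) -> str:
        return (f"SlopeSummary(mean={self.mean:.4f}, "
                f"cri=[{self.cri_low:.4f}, {self.cri_high:.4f}], "
                f"p_negative={self.p_negative:.3f}, scale={self.scale})")


def _survival_trajectories(results, sex, scale, reference, n_draws):
    from .survival import MODEL1

    model = results.model
    draws = results.draws if n_draws is None else results.draws.thin_to(n_draws)
    A = model.age_cap
    if reference is None:
        eps = 0.0
    else:
        if reference not in model.pop_ids:
            raise KeyError(f"unknown reference population {reference!r}")
        eps = draws.get(f"eps_pop[{reference}]")[:, None]

    def logit_traj(sx: str) -> np.ndarray:
        if model.variant == MODEL1:
            cols = np.column_stack([draws.get(f"alpha[{a},{sx}]") for a in range(1, A + 1)])
            return cols + eps
        cols = np.column_stack([draws.get(f"alpha[{a}]") for a in range(1, A + 1)])
        # female is the reference sex; males add the mean contrast d (or the
        # reference population's own b when a population is named)
        if sx == "male":
            contrast = (draws.get(f"b[{reference}]") if reference is not None
                        else draws.get("d"))[:, None]
            cols = cols + contrast
        return cols + eps

    if sex in ("female", "male"):
        lt = logit_traj(sex)
        return lt if scale == "logit" else expit(lt)
    if sex != "both":
        raise ValueError("sex must be 'female', 'male' or 'both'")
    pf, pm = expit(logit_traj("female")), expit(logit_traj("male"))
    avg = 0.5 * (pf + pm)  # sexes averaged on the probability scale
    if scale == "probability":
        return avg
    return np.log(avg / (1.0 - avg))


def _breeding_trajectories(results, sex, scale, n_draws):
    model = results.model
    draws = results.draws if n_draws is None else results.draws.thin_to(n_draws)
    A = model.age_cap
    if sex in ("female", "male"):
        if not model.stratify:
            raise ValueError(
                "sex-specific breeding trajectories require the sex-stratified variant")
        lt = np.column_stack([draws.get(f"alpha_bs[{a},{sex}]") for a in range(1, A + 1)])
        return lt if scale == "logit" else expit(lt)
    if sex != "both":
        raise ValueError("sex must be 'female', 'male' or 'both'")
    if model.stratify:
        pf = expit(np.column_stack([draws.get(f"alpha_bs[{a},female]") for a in range(1, A + 1)]))
        pm = expit(np.column_stack([draws.get(f"alpha_bs[{a},male]") for a in range(1, A + 1)]))
        avg = 0.5 * (pf + pm)
        return avg if scale == "probability" else np.log(avg / (1.0 - avg))
    lt = np.column_stack([draws.get(f"alpha_bs[{a}]") for a in range(1, A + 1)])
    return lt if scale == "logit" else expit(lt)


def age_trajectory(
    results,
    which: str = "survival",
    sex: str = "both",
    scale: str = "probability",
    reference: str | None = None,
    n_draws: int | None = None,
) -> np.ndarray:
    """Per-draw age-class rate matrix (n_draws x n_age_classes).

    ``reference`` selects a named population's random effect (None =
    population average, effect 0); the individual effect is always 0.
    ``sex='both'`` averages the two sexes' predictors on the probability
    scale.  ``n_draws`` uniformly thins the retained draws first.
    """
    if scale not in ("probability", "logit"):
        raise ValueError("scale must be 'probability' or 'logit'")
    if which == "survival":
        return _survival_trajectories(results, sex, scale, reference, n_draws)
    if which == "breeding":
        return _breeding_trajectories(results, sex, scale, n_draws)
    raise ValueError("which must be 'survival' or 'breeding'")


def slope_distribution(trajectories: np.ndarray, ages, scale: str = "probability") -> SlopeSummary:
    """Per-draw OLS slope of rate on age, summarized.

    The regression is unweighted; exact zero slopes split evenly between the
    negative and positive tallies so a constant trajectory gives
    p(slope < 0) = 0.5.
    """
    traj = np.atleast_2d(np.asarray(trajectories, dtype=float))
    ages = np.asarray(ages, dtype=float)
    if ages.size < 2 or np.unique(ages).size < 2:
        raise ValueError("slope regression requires at least 2 distinct ages")
    if traj.shape[1] != ages.size:
        raise ValueError("trajectory width must match the number of ages")
    if traj.shape[0] < 100:
        warnings.warn("fewer than 100 posterior draws; slope summaries will be noisy",
                      stacklevel=2)
    xc = ages - ages.mean()
    slopes = traj @ xc / (xc @ xc)
    n = slopes.size
    p_neg = ((slopes < 0).sum() + 0.5 * (slopes == 0).sum()) / n
    return SlopeSummary(
        slope_draws=slopes,
        mean=float(slopes.mean()),
        cri_low=float(np.percentile(slopes, 2.5)),
        cri_high=float(np.percentile(slopes, 97.5)),
        p_negative=float(p_neg),
        scale=scale,
    )


def plot_age_trajectory(trajectories: np.ndarray, ages, path=None, ylabel: str = "rate"):
    """Posterior-mean age trajectory with a 95% band and the fitted line.

    Returns the matplotlib figure; writes it to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traj = np.atleast_2d(trajectories)
    ages = np.asarray(ages, dtype=float)
    mean = traj.mean(axis=0)
    lo, hi = np.percentile(traj, [2.5, 97.5], axis=0)
    s = slope_distribution(traj, ages)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.fill_between(ages, lo, hi, alpha=0.2, color="grey", label="95% CrI")
    ax.plot(ages, mean, "o", mfc="white", color="black", label="posterior mean")
    xb = ages.mean()
    yb = mean.mean()
    ax.plot(ages, yb + s.mean * (ages - xb), "-", color="black",
            label=f"slope {s.mean:.3f} (p<0: {s.p_negative:.2f})")
    ax.set_xlabel("age class")
    ax.set_ylabel(ylabel)
    ax.set_xticks(ages)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def table_of_slopes(rows: dict[tuple[str, str], SlopeSummary]) -> pd.DataFrame:
    """Assemble a summary table (trait x sex rows) from slope summaries.

    ``rows`` maps (trait, sex) -> SlopeSummary, e.g. ("Survival", "Male").
    """
    data = []
    for (trait, sex), s in rows.items():
        data.append({"trait": trait, "sex": sex, "mean_slope": s.mean,
                     "cri_low": s.cri_low, "cri_high": s.cri_high,
                     "p_slope_negative": s.p_negative, "scale": s.scale})
    return pd.DataFrame(data)
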