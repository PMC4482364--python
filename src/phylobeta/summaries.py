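"""Reporting surfaces: posterior tables, decline tabulations, descriptives.

Posterior summaries mirror the study's report tables: posterior mean, Monte
Carlo standard error of the mean, 95% highest-posterior-density interval,
effective sample size and split-chain R-hat per parameter, with a *notable*
flag for coefficients whose 95% HPDI excludes zero. The dispersion gamma and
Pagel's lambda are always reported rows; a sign test is meaningless for
positive-support parameters, so they are flagged as model parameters rather
than sign-tested.

Descriptive surfaces: region-by-decline-category counts, per-genus incidence
of decline (species deduplicated across regions — a species that declined in
either region counts once, as declining), and per-region mean +/- SE of raw
female body mass.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .mcmc import ChainSet, effective_sample_size, gelman_rubin, hpd_interval, mcse
from .traits import DECLINE_CATEGORIES, TraitTable, categorize_decline

logger = logging.getLogger(__name__)

__all__ = [
    "summarize_posterior",
    "tabulate_declines",
    "genus_incidence",
    "regional_descriptives",
    "binned_decline_summary",
    "render_table",
]


def _parameter_kind(name: str) -> str:
    if name == "gamma":
        return "dispersion"
    if name == "lambda":
        return "signal"
    if name.startswith("u["):
        return "random_effect"
    return "coefficient"


def summarize_posterior(chains: ChainSet, mass: float = 0.95,
                        include_random_effects: bool = False) -> pd.DataFrame:
    """One summary row per parameter from the combined inference chain.

    Columns: mean, sd, mcse, hpdi_low, hpdi_high, ess, rhat, kind, notable.
    ``notable`` is True for a coefficient whose HPDI excludes zero and for
    the always-reported gamma/lambda rows; random effects are excluded by
    default.
    """
    if chains.n_keep == 0:
        raise ValueError("empty chains")
    rows = []
    for name in chains.names:
        kind = _parameter_kind(name)
        if kind == "random_effect" and not include_random_effects:
            continue
        draws = chains.combined(name)
        low, high = hpd_interval(draws, mass)
        if kind == "coefficient":
            notable = not (low <= 0.0 <= high)
        elif kind in ("dispersion", "signal"):
            notable = True
        else:
            notable = not (low <= 0.0 <= high)
        rows.append({
            "parameter": name,
            "mean": float(draws.mean()),
            "sd": float(draws.std(ddof=1)),
            "mcse": mcse(draws),
            "hpdi_low": low,
            "hpdi_high": high,
            "ess": effective_sample_size(draws),
            "rhat": gelman_rubin(chains.parameter(name)),
            "kind": kind,
            "notable": bool(notable),
        })
    return pd.DataFrame(rows)


def tabulate_declines(table: TraitTable) -> pd.DataFrame:
    """Counts of analysis taxa by region and decline category, with totals."""
    df = table.data
    regions = ("north", "south")
    out = {}
    for region in regions:
        sub = df[df["region"].astype(str).str.lower() == region]
        cats = categorize_decline(sub["decline"].to_numpy(dtype=float)) \
            if len(sub) else np.array([], dtype=object)
        counts = {cat: int(np.sum(cats == cat)) for cat in DECLINE_CATEGORIES}
        counts["Total"] = int(len(sub))
        out[region] = counts
    result = pd.DataFrame(out).T[list(DECLINE_CATEGORIES) + ["Total"]]
    result.index.name = "region"
    return result


def genus_incidence(table: TraitTable) -> pd.DataFrame:
    """Per-genus counts of declining (y > 0) vs stable (y = 0) species.

    Species are deduplicated across regions: a species that declined in any
    region counts once as declining. Empty genus labels are grouped under
    'unknown' with a warning.
    """
    df = table.data.copy()
    genus = df["genus"].astype(object)
    blank = genus.isna() | (genus.astype(str).str.strip() == "")
    if blank.any():
        logger.warning("%d rows with empty genus grouped under 'unknown'",
                       int(blank.sum()))
        genus = genus.where(~blank, "unknown")
    df["genus"] = genus
    per_species = df.groupby("species").agg(
        genus=("genus", "first"),
        declined=("decline", lambda y: bool((np.asarray(y) > 0).any())),
    )
    out = per_species.groupby("genus")["declined"].agg(
        n_declining="sum", n_stable=lambda s: int((~s).sum())
    ).astype(int).reset_index()
    return out


def regional_descriptives(table: TraitTable,
                          column: str = "female_mass_g") -> pd.DataFrame:
    """Per-region arithmetic mean, SE (sd/sqrt(n)) and n of a raw trait."""
    df = table.data
    rows = []
    for region in ("north", "south"):
        vals = df.loc[
            df["region"].astype(str).str.lower() == region, column
        ].dropna().to_numpy(dtype=float)
        n = vals.size
        mean = float(vals.mean()) if n else float("nan")
        if n >= 2:
            se = float(vals.std(ddof=1) / np.sqrt(n))
            flagged = False
        else:
            se = float("nan")
            flagged = True
            logger.warning("region %s has %d values for %s: SE undefined",
                           region, n, column)
        rows.append({"region": region, "mean": mean, "se": se, "n": n,
                     "se_undefined": flagged})
    return pd.DataFrame(rows)


def binned_decline_summary(table: TraitTable, by: str = "habitat_openness",
                           bins: int = 5) -> pd.DataFrame:
    """Mean decline and taxon counts per region within predictor bins.

    With ``by='habitat_openness'`` each rank is its own bin; continuous
    predictors are cut into ``bins`` equal-width log-scale classes. Intended
    for CSV export and plotting.
    """
    df = table.data.copy()
    if by == "habitat_openness":
        df["bin"] = df[by].astype(int).astype(str)
    else:
        logs = np.log10(df[by].to_numpy(dtype=float))
        df["bin"] = pd.cut(logs, bins=bins).astype(str)
    out = (df.groupby(["region", "bin"], observed=True)
             .agg(mean_decline=("decline", "mean"), n=("decline", "size"))
             .reset_index())
    return out


def render_table(df: pd.DataFrame, float_fmt: str = "{:.4f}") -> str:
    """Aligned plain-text rendering of a summary table."""
    show = df.copy()
    for col in show.columns:
        if pd.api.types.is_float_dtype(show[col]):
            show[col] = show[col].map(
                lambda v: float_fmt.format(v) if pd.notna(v) else "")
    return show.to_string(index=False)
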