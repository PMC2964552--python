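"""Reading and writing the per-locus summary table of the nine-locus panel.

The package ships the published observed table (one row per locus per
species: lengths, sample size, S, pi, theta_w, neutrality tests, rho, Rm,
haplotype statistics) which serves as the observation vector for the
approximate Bayesian analyses when the underlying alignments are not
available.  The same schema is emitted by the synthetic-data generator, so
observed and synthetic observations are interchangeable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .coalescent import LocusSpec

SUMMARY_COLUMNS = [
    "species", "locus", "length", "silent", "n", "S", "pi", "pi_silent",
    "theta_w", "theta_w_silent", "tajima_D", "fuli_Dstar", "fuli_Fstar",
    "rho", "Rm", "Hap", "Hdiv",
]

SPECIES = ("wild", "cultivated")


@dataclass
class Observation:
    """Cross-locus observation for one species: the per-locus table plus the
    means and (ddof=1) variances that the rejection algorithms compare."""

    species: str
    table: pd.DataFrame
    means: dict[str, float]
    variances: dict[str, float]

    @property
    def n_loci(self) -> int:
        return len(self.table)

    @property
    def mean_theta(self) -> float:
        return self.means["theta_w"]


def read_summary_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["Na", "NA", "nan"])
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    return df


def write_summary_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="Na", float_format="%.6g")


def observed_table_path() -> Path:
    return Path(resources.files("milletpop").joinpath("data/observed_panel.tsv"))


_STAT_COLS = ("S", "pi", "Hap", "Hdiv", "rho", "theta_w")


def load_observed_from_table(path: str | Path | None = None
                             ) -> dict[str, Observation]:
    """Load per-species observations from a summary table (default: the
    packaged published table).

    Means and variances are taken across loci; 'Na' cells (inestimable
    rho) are skipped in the rho mean, matching the published averaging.
    A single-locus table is an error because the cross-locus variance is
    undefined.
    """
    df = read_summary_table(path or observed_table_path())
    out: dict[str, Observation] = {}
    for species in df["species"].unique():
        sub = df[df["species"] == species].reset_index(drop=True)
        if len(sub) < 2:
            raise ValueError(
                f"{species}: need >= 2 loci for cross-locus variances")
        means = {c: float(sub[c].mean(skipna=True)) for c in _STAT_COLS}
        variances = {c: float(sub[c].var(ddof=1, skipna=True)) for c in _STAT_COLS}
        out[species] = Observation(species=species, table=sub, means=means,
                                   variances=variances)
    return out


def panel_locus_specs(observed: dict[str, Observation] | None = None
                      ) -> list[LocusSpec]:
    """Per-locus simulation geometry of the panel (lengths and sample sizes
    for both species), derived from a two-species observation."""
    observed = observed or load_observed_from_table()
    wild, cult = observed["wild"].table, observed["cultivated"].table
    cult = cult.set_index("locus")
    specs = []
    for _, row in wild.iterrows():
        crow = cult.loc[row["locus"]]
        specs.append(LocusSpec(
            locus_id=str(row["locus"]),
            L_wild=float(row["length"]),
            L_cult=float(crow["length"]),
            n_wild=int(row["n"]),
            n_cult=int(crow["n"]),
            L_silent=float(row["silent"]),
            theta_site=float(row["theta_w"]),
        ))
    return specs


def species_locus_specs(obs: Observation) -> list[tuple[str, int, float]]:
    """(locus, n, L) triples for single-population simulations."""
    return [(str(r["locus"]), int(r["n"]), float(r["length"]))
            for _, r in obs.table.iterrows()]
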