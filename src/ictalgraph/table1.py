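"""Cohort demographics table and its summary statistics.

The packaged fixture (``data/table1.tsv``) transcribes the demographics of a
31-child drug-resistant-epilepsy surgical cohort: sex, age at surgery, MRI
findings, seizure-onset type (slow SSO vs fast FSO), laterality and Engel
surgical outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import scipy.stats

from .cohort import engel_outcome

__all__ = ["load_table1", "table1_statistics", "Table1Summary"]

_REQUIRED = ["sex", "age_years", "mri_findings", "onset_type", "engel", "laterality"]


def load_table1() -> pd.DataFrame:
    """Load the packaged demographics table."""
    with resources.files("ictalgraph").joinpath("data/table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass(frozen=True)
class Table1Summary:
    n_patients: int
    median_age: float
    pct_sso: float
    pct_left: float
    n_good: int
    pct_normal_mri: float
    fisher_p_onset_vs_outcome: float


def table1_statistics(table: pd.DataFrame | None = None) -> Table1Summary:
    """Summary statistics of the demographics table.

    Returns the median age at surgery, the percentages of slow-onset (SSO)
    and left-lateralized patients, the Engel-I ("good outcome") count, the
    percentage of patients with normal MRI, and the two-sided Fisher exact
    p-value for the association of onset type (SSO/FSO) with outcome
    (Engel I vs II-IV).
    """
    if table is None:
        table = load_table1()
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"demographics table is missing columns: {missing}")
    n = len(table)
    outcome = table["engel"].map(engel_outcome)
    onset = table["onset_type"].str.upper()
    sso = onset == "SSO"
    good = outcome == "good"
    contingency = np.array(
        [
            [int((sso & good).sum()), int((sso & ~good).sum())],
            [int((~sso & good).sum()), int((~sso & ~good).sum())],
        ]
    )
    _, fisher_p = scipy.stats.fisher_exact(contingency, alternative="two-sided")
    return Table1Summary(
        n_patients=n,
        median_age=float(table["age_years"].median()),
        pct_sso=float(100.0 * sso.mean()),
        pct_left=float(100.0 * (table["laterality"].str.upper() == "L").mean()),
        n_good=int(good.sum()),
        pct_normal_mri=float(
            100.0 * table["mri_findings"].str.startswith("Normal").mean()
        ),
        fisher_p_onset_vs_outcome=float(fisher_p),
    )
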