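"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from repseq_compare.clonotype_io import Repertoire


def make_repertoire(
    counts,
    sample_id: str = "S",
    patient_id: str = "P",
    tissue: str = "tumor",
    keys=None,
) -> Repertoire:
    """Minimal repertoire with synthetic clone keys and the given counts."""
    counts = np.asarray(counts, dtype=np.int64)
    if keys is None:
        keys = [f"clone{i:07d}" for i in range(len(counts))]
    table = pd.DataFrame(
        {
            "cdr3_nt": keys,
            "cdr3_aa": [f"aa_{k}" for k in keys],
            "v_segment": ["TRBV9"] * len(counts),
            "j_segment": ["TRBJ2-1"] * len(counts),
            "count": counts,
        }
    )
    return Repertoire(
        sample_id=sample_id, patient_id=patient_id, tissue=tissue, table=table, key_level="nt+VJ"
    )


@pytest.fixture
def rep_factory():
    return make_repertoire


def brute_force_wilcoxon_p(diffs) -> float:
    """Two-tailed signed-rank p by literal enumeration of all sign vectors."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    w_obs = ranks[d > 0].sum()
    dev = abs(w_obs - total / 2)
    hits = 0
    for signs in itertools.product([False, True], repeat=n):
        w = ranks[np.array(signs)].sum()
        if abs(w - total / 2) >= dev - 1e-12:
            hits += 1
    return hits / 2**n


def brute_force_mwu_p(a, b) -> float:
    """Two-tailed Mann-Whitney p by enumeration of all group labelings."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = stats.rankdata(pooled)
    center = n_a * len(b) / 2
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    dev = abs(u_obs - center)
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        u = ranks[list(comb)].sum() - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - center) >= dev - 1e-12:
            hits += 1
    return hits / total


# Printed clinical table for the 15-patient lung cancer cohort (age, sex,
# histology, differentiation, TNM).  Survival columns are intentionally
# absent: they are unpublished and supplied synthetically where needed.
CLINICAL_TABLE_TSV = """\
patient_id\tage\tsex\tpath_type\tdifferentiation\ttnm_stage
P1\t62\tMale\tADC\tL\tT3N2M0 (III)
P2\t56\tFemale\tADC\tL\tT2bN0M0 (I)
P3\t57\tMale\tADC\tL\tT2aN0M0 (I)
P4\t43\tFemale\tADC\tH\tT1N0M0 (I)
P5\t73\tMale\tSCC\tL\tT2aN2M0 (III)
P6\t65\tMale\tSCLC\t–\tT2aN0M0 (I)
P7\t76\tMale\tSCC\tM\tT1aN1M0 (II)
P8\t73\tMale\tADC\tL\tT2aN2M0 (III)
P9\t64\tMale\tADC\tL\tT2bN0M0 (II)
P10\t56\tFemale\tADC\tM\tT2aN0M0 (I)
P11\t64\tMale\tADC\tM\tT1N0M0 (I)
P12\t31\tMale\tADC\tL\tT3N2M0 (III)
P13\t61\tFemale\tADC\tM\tT2N0M0 (I)
P14\t73\tFemale\tADC\tH\tT1aN0M0 (I)
P15\t41\tMale\tADC\tL\tT2N2M0 (III)
"""


@pytest.fixture
def clinical_table(tmp_path):
    path = tmp_path / "metadata.tsv"
    path.write_text(CLINICAL_TABLE_TSV)
    return path
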