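import dataclasses

import numpy as np
import pandas as pd
import pytest

import ipfkinome as ik


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """A scaled-down study layout for fast unit tests."""
    return dataclasses.replace(
        ik.default_study_config(seed=99),
        n_genes=40, n_cancer_related=8, n_inhibitor_flagged=8,
        n_induced=4, n_suppressed=2)


@pytest.fixture
def small_dataset(small_config):
    return ik.simulate_dataset(small_config)


@pytest.fixture
def tiny_panel():
    return ik.GenePanel(pd.DataFrame({
        "transcript_length_bp": [1000, 2000, 500, 1500, 800],
        "category": ["kinase", "kinase", "kinase", "cancer_related", "kinase"],
        "inhibitor_available": [True, False, True, False, False],
    }, index=pd.Index(["KA", "KB", "KC", "CD", "KE"], name="gene_id")))


@pytest.fixture
def tiny_sheet():
    """Two multi-sample IPF patients, one single-sample, two controls."""
    return ik.SampleSheet(pd.DataFrame({
        "patient_id": ["P1", "P1", "P1", "P1", "P2", "P2", "P3",
                       "C1", "C1", "C2", "C2"],
        "group": ["IPF"] * 7 + ["control"] * 4,
        "ashcroft_score": [7, 6, 3, 4, 7, 3, 6,
                           None, None, None, None],
        "segment_label": [f"seg{i}" for i in range(11)],
    }, index=pd.Index([f"S{i}" for i in range(11)], name="sample_id")))


@pytest.fixture
def tiny_expr(rng, tiny_sheet, tiny_panel):
    values = rng.lognormal(3.0, 1.0, (5, 11))
    return ik.ExpressionMatrix(pd.DataFrame(
        values, index=tiny_panel.genes, columns=tiny_sheet.samples))
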