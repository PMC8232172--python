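import numpy as np
import pandas as pd
import pytest

from cumulostrat import FeatureAnnotation, OmicsMatrix, RegulatorNetwork, SampleSheet


def make_matrix(values, feature_ids=None, sample_ids=None, modality="expression"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(n)]
    sample_ids = sample_ids or [f"s{j}" for j in range(p)]
    return OmicsMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids), modality)


def make_network(edges):
    """edges: iterable of (regulator, target, sign)."""
    return RegulatorNetwork(
        pd.DataFrame(
            [(r, "hormone", t, s) for r, t, s in edges],
            columns=["regulator_id", "regulator_class", "target_gene", "sign"],
        )
    )


def make_annotation(rows):
    """rows: iterable of (feature_id, gene_symbol, tss_offset_bp or None)."""
    return FeatureAnnotation(
        pd.DataFrame(
            [(f, g, "chr1", "+", off) for f, g, off in rows],
            columns=["feature_id", "gene_symbol", "chromosome", "strand", "tss_offset_bp"],
        )
    )


@pytest.fixture
def tiny_sheet():
    rows = []
    for ci, (cycle, donor, outcome) in enumerate(
        [("VS1", "D1", "positive"), ("VS2", "D2", "negative"), ("VS3", "D3", "negative")]
    ):
        for k in range(2):
            rows.append((f"{cycle}c{k + 1}", donor, cycle, "long", outcome, k + 1))
    return SampleSheet(
        pd.DataFrame(
            rows,
            columns=["cluster_id", "donor_id", "cycle_id", "protocol", "outcome", "oocyte_index"],
        )
    )
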