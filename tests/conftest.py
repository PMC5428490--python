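import numpy as np
import pytest

from heterosis import RelationConfig, SampleDesign, TrioExpressionSet


@pytest.fixture
def exact_cfg():
    """Exact-ratio arithmetic: no pseudocount."""
    return RelationConfig(pseudocount=0.0)


def make_trio(values, tissue="mesocarp", stage="3.5MAF", n_reps=3):
    """Trio set from a genes x 3 array of group means, replicated exactly."""
    values = np.asarray(values, dtype=float)
    gene_ids = [f"g{i + 1}" for i in range(values.shape[0])]
    design = [
        SampleDesign(f"{grp}_r{j + 1}", grp, tissue, stage)
        for grp in ("parentA", "parentB", "hybrid")
        for j in range(n_reps)
    ]
    matrix = np.repeat(values, n_reps, axis=1)
    return TrioExpressionSet(
        gene_ids=gene_ids, values=matrix, design=design, tissue=tissue, stage=stage
    )


@pytest.fixture
def trio_files(tmp_path):
    """A 3-gene x 9-sample matrix/design pair on disk."""
    matrix = tmp_path / "matrix.tsv"
    design = tmp_path / "design.tsv"
    samples = [
        ("pA1", "parentA"), ("pA2", "parentA"), ("pA3", "parentA"),
        ("pB1", "parentB"), ("pB2", "parentB"), ("pB3", "parentB"),
        ("h1", "hybrid"), ("h2", "hybrid"), ("h3", "hybrid"),
    ]
    rows = [
        ("g1", [10, 11, 9, 100, 98, 102, 40, 41, 39]),
        ("g2", [5, 5, 5, 5, 5, 5, 20, 20, 20]),
        ("g3", [0, 0, 0, 1, 1, 1, 0.5, 0.5, 0.5]),
    ]
    with open(matrix, "w") as fh:
        fh.write("gene_id\t" + "\t".join(s for s, _ in samples) + "\n")
        for gene, vals in rows:
            fh.write(gene + "\t" + "\t".join(str(v) for v in vals) + "\n")
    with open(design, "w") as fh:
        fh.write("sample_id\tgroup\ttissue\tstage\n")
        for sid, grp in samples:
            fh.write(f"{sid}\t{grp}\tmesocarp\t3.5MAF\n")
    return matrix, design
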