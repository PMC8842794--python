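import numpy as np
import pandas as pd
import pytest

from pertnet.io import INTENSITY, ExpressionMatrix, SurvivalCohort


def make_deg_table(rows: dict[str, tuple[float, float, str, bool]]) -> pd.DataFrame:
    """Build a minimal DEG table from gene -> (p, log2_fc, direction, is_deg)."""
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["p", "log2_fc", "direction", "is_deg"]
    )
    df.index.name = "gene"
    df["fc"] = 2.0 ** df["log2_fc"]
    df["statistic"] = 0.0
    df["fdr"] = df["p"]
    df["degenerate"] = False
    return df


def make_cohort(times, events, expr_rows: dict[str, list[float]]) -> SurvivalCohort:
    samples = [f"s{i}" for i in range(len(times))]
    idx = pd.Index(samples, name="sample")
    expr = pd.DataFrame(expr_rows, index=samples).T
    expr.columns = samples
    return SurvivalCohort(
        time=pd.Series(times, index=idx, dtype=float),
        event=pd.Series(events, index=idx, dtype=int),
        expression=expr,
    )


@pytest.fixture
def small_intensity_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(20)]
    samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
    values = pd.DataFrame(
        rng.normal(8, 1, size=(20, 6)), index=genes, columns=samples
    )
    groups = {s: ("A" if s.startswith("a") else "B") for s in samples}
    return ExpressionMatrix(values=values, group_of=groups, flavor=INTENSITY)
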