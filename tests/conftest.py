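import numpy as np
import pandas as pd
import pytest

from gutevo.genome_analysis import MutationTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_mutation_table(rows, clones=None):
    """Build a MutationTable from (clone, population, locus, category, region)
    tuples with filler positions/alleles."""
    records = [
        {
            "clone_id": clone,
            "population_id": pop,
            "host_id": f"M{pop}",
            "position": 1000 + 100 * i,
            "locus": locus,
            "category": category,
            "region": region,
        }
        | {"allele": f"{locus}-allele"}
        for i, (clone, pop, locus, category, region) in enumerate(rows)
    ]
    df = pd.DataFrame(
        records,
        columns=[
            "clone_id",
            "population_id",
            "host_id",
            "position",
            "locus",
            "category",
            "region",
            "allele",
        ],
    )
    return MutationTable(df, clones=clones)
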