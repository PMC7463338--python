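import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lymtrace.core import GenotypeTable, Locus, LocusPanel

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_table(
    calls: dict[str, list],
    ploidy: list[int] | None = None,
    pops: dict[str, str] | None = None,
    groups: dict[str, str] | None = None,
    eggmass: dict[str, str] | None = None,
) -> GenotypeTable:
    """Tiny-table factory: calls maps individual -> per-locus cells, each a
    string of single-character alleles ('AB'), a tuple, or None."""
    n_loci = len(next(iter(calls.values())))
    ploidy = ploidy or [2] * n_loci
    panel = LocusPanel(
        [
            Locus(f"L{j + 1}", "ACGT" * 10, (1, 10_000), ploidy=p)
            for j, p in enumerate(ploidy)
        ]
    )
    arr = np.empty((len(calls), n_loci), dtype=object)
    for i, (_ind, row) in enumerate(calls.items()):
        for j, cell in enumerate(row):
            if cell is None:
                arr[i, j] = None
            elif isinstance(cell, tuple):
                arr[i, j] = tuple(sorted(cell))
            else:
                arr[i, j] = tuple(sorted(cell))
    return GenotypeTable(
        list(calls), panel, arr, pop=pops, group=groups, eggmass=eggmass
    )


@pytest.fixture(scope="session")
def hybrid_reference():
    """Session-wide five-class hybrid reference at the calibrated parental
    differentiation (shared by assignment and hybrid tests)."""
    from lymtrace.simulate import hybrid_study_model, simulate_hybrid_study

    model = hybrid_study_model(seed=11)
    return simulate_hybrid_study(model, seed=12)


@pytest.fixture(scope="session")
def structured_panel_table():
    """Four well-differentiated reference groups (F = 0.2 each, 40 loci)."""
    from lymtrace.simulate import build_cluster_model, simulate_genotypes

    model = build_cluster_model(40, 8, [0.2] * 4, seed=21)
    tab = simulate_genotypes(
        model, [30] * 4, pop_names=["chn", "adm", "jap", "umb"], seed=22
    )
    return model, tab
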