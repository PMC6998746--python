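import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from panelcnv import (
    DepthMatrix,
    Panel,
    Target,
    apply_mask,
    demo_panel,
    make_bins,
    make_target_groups,
)

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def build_panel(genes: dict[str, list[int]], bin_size: int = 200,
                window_sizes=(2, 4, 8), mask=()) -> Panel:
    """Small synthetic panel from {gene: [exon lengths]} specs."""
    targets = []
    pos = 1000
    for gi, (gene, lengths) in enumerate(genes.items()):
        chrom = f"chr{gi + 1}"
        pos = 1000
        for e, ln in enumerate(lengths, start=1):
            targets.append(Target(f"{gene}|ex{e}", gene, chrom, pos, pos + ln,
                                  kind="exon", exon_index=e))
            pos += ln + 500
    panel = make_target_groups(make_bins(Panel("mini", targets), bin_size),
                               window_sizes=window_sizes)
    if mask:
        panel = apply_mask(panel, mask)
    return panel


@pytest.fixture(scope="session")
def mini_panel() -> Panel:
    """Three small genes; GENE1 has a >bin_size exon to exercise binning."""
    return build_panel({
        "GENE1": [500, 120, 400, 150, 210],
        "GENE2": [180, 90, 260],
        "GENE3": [220, 310],
    })


@pytest.fixture(scope="session")
def demo() -> Panel:
    return demo_panel()


def depth_from_array(arr, target_ids, specimen_ids, batches=None) -> DepthMatrix:
    values = pd.DataFrame(np.asarray(arr, dtype=float), index=target_ids,
                          columns=specimen_ids)
    labels = None
    if batches is not None:
        labels = pd.Series(batches, index=specimen_ids)
    return DepthMatrix(values=values, batch_labels=labels)
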