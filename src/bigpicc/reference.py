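"""Literature-derived hit ranges per cancer type.

The number of hits required for carcinogenesis is hypothesised to depend
on the cancer type (2 for glioblastoma up to 8 for papillary kidney
cancer). These ranges are user inputs to the pipeline, not defaults; the
bundled table is a convenience reference.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_hit_ranges", "parse_hit_range"]


def load_hit_ranges() -> pd.DataFrame:
    """Reference table of per-cancer-type hit ranges.

    Columns: ``abbreviation``, ``cancer_type``, ``hit_ranges`` (semicolon-
    separated list of single values or ``l-u`` ranges).
    """
    with resources.files("bigpicc").joinpath("data/hit_ranges.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def parse_hit_range(spec: str) -> tuple[int, int]:
    """Parse a single entry like ``"5"`` or ``"6-7"`` into (l, u)."""
    parts = spec.split("-")
    if len(parts) == 1:
        l = u = int(parts[0])
    elif len(parts) == 2:
        l, u = int(parts[0]), int(parts[1])
    else:
        raise ValueError(f"cannot parse hit range {spec!r}")
    if not 1 <= l <= u:
        raise ValueError(f"invalid hit range {spec!r}")
    return l, u
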