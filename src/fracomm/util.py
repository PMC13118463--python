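"""Small shared helpers: seeding, deterministic TSV output, logging setup."""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("fracomm")

#: float format used for every numeric TSV so reruns are byte-identical
FLOAT_FORMAT = "%.10g"


def derive_seed(seed: int, label: str) -> int:
    """Derive a stable child seed (< 2**31) from a root seed and a stage label.

    Each pipeline stage draws from its own stream so that running stages
    individually or through ``run_pipeline`` gives identical randomness.
    """
    tag = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence([int(seed), int(tag)])
    return int(ss.generate_state(1)[0] % (2**31))


def rng_from(seed: int, label: str = "") -> np.random.Generator:
    if label:
        seed = derive_seed(seed, label)
    return np.random.default_rng(seed)


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        Path(logfile).parent.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
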