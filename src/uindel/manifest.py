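"""Run provenance: config hash, input checksums, strategies, seeds.

Every TSV the pipeline writes carries the manifest hash in a leading comment
line so outputs can be traced back to the exact configuration that produced
them.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import pandas as pd

from . import __version__


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    sample_totals: dict = field(default_factory=dict)  # id -> {standard, nonstandard}
    strategies: dict = field(default_factory=dict)
    version: str = __version__

    @property
    def config_hash(self) -> str:
        return sha256_obj(self.config)

    @property
    def hash(self) -> str:
        return sha256_obj(
            {
                "version": self.version,
                "config": self.config,
                "seeds": self.seeds,
                "inputs": self.input_checksums,
                "strategies": self.strategies,
            }
        )

    def add_input(self, path) -> None:
        self.input_checksums[os.path.basename(str(path))] = sha256_file(path)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "manifest_hash": self.hash,
            "config": self.config,
            "seeds": self.seeds,
            "input_checksums": self.input_checksums,
            "sample_totals": self.sample_totals,
            "strategies": self.strategies,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_tsv(self, df: pd.DataFrame, path) -> None:
        """Write a TSV with the manifest hash as a leading comment line."""
        with open(path, "w") as fh:
            fh.write(f"# manifest_hash={self.hash}\n")
            df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    """Read a pipeline TSV, skipping manifest comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")
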