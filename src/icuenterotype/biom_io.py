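"""Minimal BIOM 2.1 (HDF5) reading and writing via h5py.

Covers the subset of the format the pipeline needs: observation and sample id
lists plus the sparse count matrix in both orientations.  Observation ids hold
the ';'-separated lineage strings.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import sparse


def read_biom(path: str | Path, mode: str | None = None):
    from .abundance import table_from_frame

    with h5py.File(path, "r") as f:
        obs_ids = [s.decode() if isinstance(s, bytes) else str(s)
                   for s in f["observation/ids"][:]]
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in f["sample/ids"][:]]
        grp = f["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(obs_ids), len(sample_ids)),
        )
    frame = pd.DataFrame(mat.toarray().T, index=sample_ids, columns=obs_ids)
    return table_from_frame(frame, mode=mode)


def write_biom(table, path: str | Path) -> None:
    dense = table.values().T  # observations x samples
    csr = sparse.csr_matrix(dense)
    csc = sparse.csc_matrix(dense)
    with h5py.File(path, "w") as f:
        f.attrs["id"] = "No Table ID"
        f.attrs["type"] = "OTU table"
        f.attrs["format-url"] = "http://biom-format.org"
        f.attrs["format-version"] = np.array([2, 1], dtype=np.int64)
        f.attrs["generated-by"] = "icuenterotype"
        f.attrs["creation-date"] = datetime.datetime.now().isoformat()
        f.attrs["shape"] = np.array(dense.shape, dtype=np.int64)
        f.attrs["nnz"] = int(csr.nnz)
        str_dt = h5py.string_dtype()
        f.create_dataset("observation/ids",
                         data=np.array(list(table.data.columns), dtype=str_dt))
        f.create_dataset("sample/ids",
                         data=np.array(list(table.data.index), dtype=str_dt))
        for name, m in (("observation", csr), ("sample", csc)):
            g = f.create_group(f"{name}/matrix")
            g.create_dataset("data", data=m.data.astype(float))
            g.create_dataset("indices", data=m.indices.astype(np.int64))
            g.create_dataset("indptr", data=m.indptr.astype(np.int64))
        for name in ("observation", "sample"):
            f.create_group(f"{name}/metadata")
            f.create_group(f"{name}/group-metadata")
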