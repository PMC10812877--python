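"""Deterministic .npz writing.

numpy's savez stamps zip entries with the current time, so two otherwise
identical runs produce different bytes. Checkpoints and cohort archives are
written with fixed zip metadata instead: identical arrays => identical files.
The result is a regular .npz readable by numpy.load.
"""

from __future__ import annotations

import io
import zipfile

import numpy as np

_EPOCH = (1980, 1, 1, 0, 0, 0)  # earliest timestamp zip can represent


def savez_deterministic(path, **arrays) -> None:
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.save(buf, np.asarray(arrays[name]), allow_pickle=False)
            info = zipfile.ZipInfo(f"{name}.npy", date_time=_EPOCH)
            zf.writestr(info, buf.getvalue())
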