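"""Small I/O helpers: atomic text writes (write to a temp file, then rename)."""

from __future__ import annotations

import os
import tempfile
from pathlib import Path


def write_text_atomic(path, text: str) -> None:
    """Write text so the destination is never observed partially written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
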