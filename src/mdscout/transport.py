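"""Swappable transport layer.

All repository access goes through a :class:`Transport`, so harvests can run
either live (HTTP with retry/backoff and per-repository rate limiting) or
fully offline against a recorded fixture tree. Requests are addressed by a
stable hash of (repository, endpoint, parameters); the fixture tree maps
those hashes to stored JSON/HTML payloads, which makes replays byte-exact.
"""

from __future__ import annotations

import hashlib
import json
import time
import urllib.error
import urllib.parse
import urllib.request
from pathlib import Path
from typing import Any, Protocol

from .errors import MissingDatasetError, TransportError

REQUEST_INDEX = "requests.json"
RESPONSE_DIR = "responses"


def request_key(repository: str, endpoint: str, params: dict[str, Any]) -> str:
    """Canonical string identifying one API request."""
    return f"{repository}|{endpoint}|{json.dumps(params, sort_keys=True, default=str)}"


def request_hash(repository: str, endpoint: str, params: dict[str, Any]) -> str:
    key = request_key(repository, endpoint, params)
    return hashlib.sha256(key.encode()).hexdigest()[:16]


class Transport(Protocol):
    def get_json(self, repository: str, endpoint: str, params: dict[str, Any]) -> Any: ...

    def get_text(self, repository: str, endpoint: str, params: dict[str, Any]) -> str: ...

    def get_bytes(self, url: str) -> bytes: ...


class FixtureTransport:
    """Replays a recorded fixture tree; raises like a 404 on unknown requests.

    Tree layout::

        root/
          requests.json          # request key -> relative payload path
          responses/<hash>.json
          responses/<hash>.html
          files/...              # downloadable payloads (fixture:// urls)
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        index_path = self.root / REQUEST_INDEX
        if not index_path.exists():
            raise TransportError(f"no fixture index at {index_path}")
        self._index: dict[str, str] = json.loads(index_path.read_text())

    def _resolve(self, repository: str, endpoint: str, params: dict[str, Any]) -> Path:
        key = request_key(repository, endpoint, params)
        rel = self._index.get(key)
        if rel is None:
            raise MissingDatasetError(f"no recorded response for: {key}")
        return self.root / rel

    def get_json(self, repository: str, endpoint: str, params: dict[str, Any]) -> Any:
        return json.loads(self._resolve(repository, endpoint, params).read_text())

    def get_text(self, repository: str, endpoint: str, params: dict[str, Any]) -> str:
        return self._resolve(repository, endpoint, params).read_text()

    def get_bytes(self, url: str) -> bytes:
        if not url.startswith("fixture://"):
            raise TransportError(f"fixture transport cannot fetch non-fixture url: {url}")
        path = self.root / url[len("fixture://") :]
        if not path.exists():
            raise MissingDatasetError(f"no fixture payload at {url}")
        return path.read_bytes()


class FixtureWriter:
    """Records (request -> payload) pairs into a FixtureTransport-readable tree."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        (self.root / RESPONSE_DIR).mkdir(parents=True, exist_ok=True)
        self._index: dict[str, str] = {}

    def record(
        self, repository: str, endpoint: str, params: dict[str, Any], payload: Any, *, kind: str = "json"
    ) -> None:
        h = request_hash(repository, endpoint, params)
        rel = f"{RESPONSE_DIR}/{h}.{kind}"
        path = self.root / rel
        if kind == "json":
            path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        else:
            path.write_text(payload)
        self._index[request_key(repository, endpoint, params)] = rel

    def add_file(self, relative_path: str, content: bytes) -> str:
        """Store a downloadable payload; returns its fixture:// url."""
        path = self.root / "files" / relative_path
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_bytes(content)
        return f"fixture://files/{relative_path}"

    def flush(self) -> None:
        (self.root / REQUEST_INDEX).write_text(json.dumps(self._index, indent=1, sort_keys=True))


#: Live API roots; used only in live mode, never during offline replay.
API_ROOTS = {
    "zenodo": "https://zenodo.org/api",
    "figshare": "https://api.figshare.com/v2",
    "osf": "https://api.osf.io/v2",
}


class HttpTransport:
    """Minimal live transport: exponential backoff, 3 attempts, rate limited."""

    def __init__(self, min_interval_s: float = 1.0, attempts: int = 3):
        self.min_interval_s = min_interval_s
        self.attempts = attempts
        self._last_call: dict[str, float] = {}

    def _url(self, repository: str, endpoint: str, params: dict[str, Any]) -> str:
        root = API_ROOTS[repository]
        query = urllib.parse.urlencode({k: str(v) for k, v in sorted(params.items())})
        return f"{root}/{endpoint}?{query}"

    def _fetch(self, url: str, repository: str) -> bytes:
        wait = time.monotonic() - self._last_call.get(repository, 0.0)
        if wait < self.min_interval_s:
            time.sleep(self.min_interval_s - wait)
        err: Exception | None = None
        for attempt in range(self.attempts):
            try:
                self._last_call[repository] = time.monotonic()
                with urllib.request.urlopen(url, timeout=30) as resp:
                    return resp.read()
            except urllib.error.HTTPError as e:
                if e.code == 404:
                    raise MissingDatasetError(url) from e
                if e.code in (401, 403, 410):
                    from .errors import AccessError

                    raise AccessError(f"{e.code} for {url}") from e
                err = e
            except urllib.error.URLError as e:
                err = e
            time.sleep(2.0**attempt)
        raise TransportError(f"failed after {self.attempts} attempts: {url}") from err

    def get_json(self, repository: str, endpoint: str, params: dict[str, Any]) -> Any:
        return json.loads(self._fetch(self._url(repository, endpoint, params), repository))

    def get_text(self, repository: str, endpoint: str, params: dict[str, Any]) -> str:
        return self._fetch(self._url(repository, endpoint, params), repository).decode()

    def get_bytes(self, url: str) -> bytes:
        host = urllib.parse.urlparse(url).netloc
        return self._fetch(url, host)
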