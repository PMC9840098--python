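"""The four-step encrypted set-intersection session.

Roles: data-holding institutions (each with a private table), a secure
computation server, and a client receiving the integrated result (one of
the institutions may act as client).  No party ever sees another's
plaintext matching keys, and the server sees only probabilistic
ciphertexts:

1. each institution hashes its matching keys, writes them into a Bloom
   filter, encrypts the filter element-wise and sends it to the server;
2. the server sums the encrypted filters homomorphically and returns the
   encrypted sum — it holds no decryption key;
3. the institutions jointly decrypt the sum (every institution must
   contribute a partial decryption), read off the positions set by all n
   parties, extract their own keys in the intersection, and send the
   payload rows of those keys to the server sealed for the client and
   tagged with an anonymous link id (a keyed digest under a secret the
   server and client do not hold);
4. the server groups the sealed rows by link id and forwards them to the
   client, which decrypts the payloads.  No key digests or identifier
   attributes reach the client.

All roles run in-process; the transcript records every message with its
byte length, so message complexity can be inspected even though the
simulation is local.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
import secrets as _secrets
from dataclasses import dataclass, field
from random import Random
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bloom as B
from . import crypto as C
from . import keys as K

__all__ = [
    "SessionConfig",
    "ProtocolMessage",
    "Transcript",
    "IntegratedResult",
    "ProtocolError",
    "run_session",
    "match_pairs_protocol",
]


class ProtocolError(Exception):
    """A session step received inconsistent or missing input."""


@dataclass(frozen=True)
class SessionConfig:
    """Static parameters of one linkage session."""

    institution_ids: tuple[str, ...]
    combo: K.AttributeCombination
    group_params: C.GroupParams = field(default_factory=C.test_params)
    client_id: str | None = None  # defaults to the first institution
    transport: str = "in_process"
    seed: int | None = None  # test mode only: reproducible transcripts
    bloom_fp_prob: float = B.DEFAULT_FP_PROB
    payload_columns: tuple[str, ...] | None = None  # None = all non-key columns

    def __post_init__(self) -> None:
        if len(self.institution_ids) < 2:
            raise ProtocolError("a session needs at least 2 institutions")
        if len(set(self.institution_ids)) != len(self.institution_ids):
            raise ProtocolError("institution ids must be distinct")
        if self.transport != "in_process":
            raise ProtocolError(
                f"transport {self.transport!r} not available; use 'in_process'"
            )
        if len(self.combo) < 2:
            raise ProtocolError("matching-key combination needs >= 2 attributes")
        if self.seed is not None and self.group_params.security_mode != "test":
            raise ProtocolError("seeded sessions are only permitted in test mode")


@dataclass(frozen=True)
class ProtocolMessage:
    sender: str
    receiver: str
    step: str  # enc_filter | summed_filter | partial_dec | enc_payload | integrated
    body: str  # serialized payload (base64/JSON, never plaintext keys)
    byte_length: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "sender": self.sender,
                "receiver": self.receiver,
                "step": self.step,
                "body_b64": base64.b64encode(self.body.encode()).decode(),
                "bytes": self.byte_length,
            },
            ensure_ascii=True,
        )


@dataclass
class Transcript:
    security_mode: str
    messages: list[ProtocolMessage] = field(default_factory=list)

    def log(self, sender: str, receiver: str, step: str, body: str) -> ProtocolMessage:
        msg = ProtocolMessage(sender, receiver, step, body, len(body.encode()))
        self.messages.append(msg)
        return msg

    @property
    def total_bytes(self) -> int:
        return sum(m.byte_length for m in self.messages)

    def byte_counts(self) -> list[tuple[str, int]]:
        return [(m.step, m.byte_length) for m in self.messages]

    def to_jsonl(self) -> str:
        header = json.dumps({"security_mode": self.security_mode})
        return "\n".join([header] + [m.to_json() for m in self.messages]) + "\n"


@dataclass
class IntegratedResult:
    """Client-side output: payload rows grouped by anonymous link id.

    Contains no matching-key digests and no identifier attributes — only
    the opaque link id, source institution labels, and payload columns.
    Groups holding several rows from one source mark a multi-record key.
    """

    groups: list[dict]

    def n_groups(self) -> int:
        return len(self.groups)


def _ct_to_wire(ct: C.Ciphertext) -> list[str]:
    return [format(ct.c1, "x"), format(ct.c2, "x")]


def _ct_from_wire(pair: Sequence[str]) -> C.Ciphertext:
    return C.Ciphertext(c1=int(pair[0], 16), c2=int(pair[1], 16))


def _link_id(key: bytes, link_secret: bytes) -> str:
    return hmac.new(link_secret, key, hashlib.sha256).hexdigest()[:32]


class _Institution:
    """One data holder: private table, key share, institutions-only secrets."""

    def __init__(
        self,
        inst_id: str,
        table: pd.DataFrame,
        cfg: SessionConfig,
        share: C.KeyShare,
        pk: C.JointPublicKey,
        bloom_params: B.BloomParams,
        link_secret: bytes,
        rng: Random | None,
    ):
        self.id = inst_id
        self.cfg = cfg
        self.share = share
        self.pk = pk
        self.bloom_params = bloom_params
        self.link_secret = link_secret
        self.rng = rng
        self.table = table.reset_index(drop=True)
        records = self.table.to_dict("records")
        self.row_keys: list[bytes] = [K.make_key(r, cfg.combo) for r in records]
        self.key_set: set[bytes] = set(self.row_keys)

    def step1_encrypt_filter(
        self, transcript: Transcript, chunk_size: int | None = None
    ) -> ProtocolMessage:
        filt = B.build_filter(self.key_set, self.bloom_params)
        cts = C.encrypt_vector(
            self.pk,
            filt.bits.tolist(),
            self.cfg.group_params,
            rng=self.rng,
            chunk_size=chunk_size,
        )
        body = json.dumps({"filter": [_ct_to_wire(c) for c in cts]})
        return transcript.log(self.id, "server", "enc_filter", body)

    def partial_decrypt_summed(
        self, summed_msg: ProtocolMessage, transcript: Transcript
    ) -> ProtocolMessage:
        cts = [_ct_from_wire(p) for p in json.loads(summed_msg.body)["summed"]]
        partials = C.partial_decrypt_vector(cts, self.share, self.cfg.group_params)
        body = json.dumps({"partials": [format(p.d, "x") for p in partials]})
        return transcript.log(self.id, "server", "partial_dec", body)

    def step3_extract_and_encrypt_payload(
        self,
        summed_msg: ProtocolMessage,
        partial_msgs: Sequence[ProtocolMessage],
        client_pub: int,
        transcript: Transcript,
    ) -> ProtocolMessage:
        params = self.cfg.group_params
        n = len(self.cfg.institution_ids)
        cts = [_ct_from_wire(p) for p in json.loads(summed_msg.body)["summed"]]
        per_inst = []
        for msg in partial_msgs:
            ds = json.loads(msg.body)["partials"]
            per_inst.append(
                [C.PartialDecryption(d=int(d, 16), institution_id=msg.sender) for d in ds]
            )
        counts = C.decode_vector(cts, per_inst, params, bound=n)
        summed = B.SummedFilter(counts=np.asarray(counts), n_institutions=n)
        in_common = B.intersect_mask(summed, list(self.key_set), self.bloom_params)

        payload_cols = self.cfg.payload_columns
        if payload_cols is None:
            key_cols = set(K.ATTRIBUTE_COLUMNS.values()) | {"person_uid"}
            payload_cols = tuple(c for c in self.table.columns if c not in key_cols)
        rows = []
        for idx, key in enumerate(self.row_keys):
            if key not in in_common:
                continue
            payload = {c: str(self.table.at[idx, c]) for c in payload_cols}
            sealed = C.seal(
                json.dumps(payload, ensure_ascii=False).encode(), client_pub, params, self.rng
            )
            rows.append(
                {
                    "link_id": _link_id(key, self.link_secret),
                    "epk": format(sealed.epk, "x"),
                    "ct_b64": base64.b64encode(sealed.ct).decode(),
                }
            )
        body = json.dumps({"rows": rows})
        return transcript.log(self.id, "server", "enc_payload", body)


class _Server:
    """The secure computation server: sums ciphertexts, relays, groups.

    Holds no decryption key and no Bloom salt; its entire view is
    probabilistic ciphertexts, partial decryptions and sealed payloads.
    """

    def __init__(self, cfg: SessionConfig):
        self.cfg = cfg

    def step2_sum(
        self, enc_msgs: Sequence[ProtocolMessage], transcript: Transcript
    ) -> dict[str, ProtocolMessage]:
        senders = {m.sender for m in enc_msgs}
        expected = set(self.cfg.institution_ids)
        if senders != expected:
            raise ProtocolError(
                f"step 2 needs one encrypted filter per institution; "
                f"missing {sorted(expected - senders)}"
            )
        vectors = []
        for m in enc_msgs:
            vectors.append([_ct_from_wire(p) for p in json.loads(m.body)["filter"]])
        summed = C.add_vectors(vectors, self.cfg.group_params)
        body = json.dumps({"summed": [_ct_to_wire(c) for c in summed]})
        return {
            inst: transcript.log("server", inst, "summed_filter", body)
            for inst in self.cfg.institution_ids
        }

    def step4_integrate(
        self, payload_msgs: Sequence[ProtocolMessage], transcript: Transcript
    ) -> ProtocolMessage:
        senders = {m.sender for m in payload_msgs}
        if senders != set(self.cfg.institution_ids):
            raise ProtocolError("step 4 needs one payload message per institution")
        grouped: dict[str, list[dict]] = {}
        for m in payload_msgs:
            for row in json.loads(m.body)["rows"]:
                grouped.setdefault(row["link_id"], []).append(
                    {"source": m.sender, "epk": row["epk"], "ct_b64": row["ct_b64"]}
                )
        body = json.dumps({"groups": [
            {"link_id": lid, "rows": rows} for lid, rows in sorted(grouped.items())
        ]})
        client = self.cfg.client_id or self.cfg.institution_ids[0]
        return transcript.log("server", client, "integrated", body)


def run_session(
    cfg: SessionConfig,
    datasets: Mapping[str, pd.DataFrame],
    chunk_size: int | None = None,
) -> tuple[IntegratedResult, Transcript]:
    """Execute steps 1-4 end to end over in-process roles.

    ``datasets`` maps institution id -> table (CSV schema columns).  The
    returned result is the client's decrypted view; the transcript holds
    every message with byte counts.  With ``cfg.seed`` set (test mode) the
    transcript is bit-reproducible.
    """
    if set(datasets) != set(cfg.institution_ids):
        raise ProtocolError("datasets must cover exactly the configured institutions")
    params = cfg.group_params
    rng = Random(cfg.seed) if cfg.seed is not None else None

    # institutions-only secrets, agreed out of band: Bloom salt + link secret
    if rng is not None:
        salt = rng.randbytes(16)
        link_secret = rng.randbytes(32)
    else:
        salt = _secrets.token_bytes(16)
        link_secret = _secrets.token_bytes(32)

    shares, pk = C.keygen(params, cfg.institution_ids, rng)
    capacity = max(1, max(len(df) for df in datasets.values()))
    bloom_params = B.params_for_capacity(capacity, salt, cfg.bloom_fp_prob)

    # client keypair for payload confidentiality from the server
    client_secret = C._rand_exponent(params.q, rng)
    client_pub = pow(params.g, client_secret, params.p)

    transcript = Transcript(security_mode=params.security_mode)
    institutions = [
        _Institution(i, datasets[i], cfg, share, pk, bloom_params, link_secret, rng)
        for i, share in zip(cfg.institution_ids, shares)
    ]
    server = _Server(cfg)

    enc_msgs = [inst.step1_encrypt_filter(transcript, chunk_size) for inst in institutions]
    summed_msgs = server.step2_sum(enc_msgs, transcript)
    partial_msgs = [
        inst.partial_decrypt_summed(summed_msgs[inst.id], transcript)
        for inst in institutions
    ]
    payload_msgs = [
        inst.step3_extract_and_encrypt_payload(
            summed_msgs[inst.id], partial_msgs, client_pub, transcript
        )
        for inst in institutions
    ]
    integrated_msg = server.step4_integrate(payload_msgs, transcript)

    # client decrypts sealed payload rows
    groups = []
    for g in json.loads(integrated_msg.body)["groups"]:
        rows = []
        for r in g["rows"]:
            box = C.SealedBox(epk=int(r["epk"], 16), ct=base64.b64decode(r["ct_b64"]))
            payload = json.loads(C.unseal(box, client_secret, params).decode())
            rows.append({"source": r["source"], **payload})
        groups.append({"link_id": g["link_id"], "rows": rows})
    return IntegratedResult(groups=groups), transcript


def match_pairs_protocol(
    screening: pd.DataFrame,
    registry: pd.DataFrame,
    combo: K.AttributeCombination,
    seed: int | None = 0,
    group_params: C.GroupParams | None = None,
) -> dict[int, set[int]]:
    """Run a 2-institution session and return matched screening->registry rows.

    Tables are tagged with a transient row-number payload column so the
    client's integrated groups can be mapped back to row indices; the
    output has the same shape as the plaintext fast path in
    :mod:`pddi.evaluation`, enabling the protocol-vs-oracle equivalence
    check.
    """
    s = screening.copy().reset_index(drop=True)
    r = registry.copy().reset_index(drop=True)
    s["_row"] = range(len(s))
    r["_row"] = range(len(r))
    cfg = SessionConfig(
        institution_ids=("screening", "registry"),
        combo=tuple(combo),
        group_params=group_params or C.test_params(),
        seed=seed,
        payload_columns=("_row",),
    )
    result, _ = run_session(cfg, {"screening": s, "registry": r})
    matched: dict[int, set[int]] = {}
    for g in result.groups:
        s_rows = [int(row["_row"]) for row in g["rows"] if row["source"] == "screening"]
        r_rows = [int(row["_row"]) for row in g["rows"] if row["source"] == "registry"]
        for si in s_rows:
            if r_rows:
                matched.setdefault(si, set()).update(r_rows)
    return matched
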