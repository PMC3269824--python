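"""64-bit global conformer identifiers (GIDs).

Layout: the low 16 bits (0x000000000000FFFF) are the local conformer id
(LID), the next 16 bits (0x00000000FFFF0000) the version (zero for compound
conformers, nonzero for deposited substance conformers), and the high 32
bits (0xFFFFFFFF00000000) the structure id (CID when version is zero, SID
otherwise).  Hex rendering is zero-padded to 16 digits.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["GlobalConformerId", "encode_gid", "decode_gid", "gid_to_hex", "gid_from_hex"]

_MASK16 = 0xFFFF
_MASK32 = 0xFFFFFFFF


@dataclass(frozen=True)
class GlobalConformerId:
    structure_id: int
    version: int
    local_id: int

    def __post_init__(self) -> None:
        if not (0 <= self.structure_id <= _MASK32):
            raise ValueError("structure_id out of 32-bit range")
        if not (0 <= self.version <= _MASK16):
            raise ValueError("version out of 16-bit range")
        if not (0 <= self.local_id <= _MASK16):
            raise ValueError("local_id out of 16-bit range")

    @property
    def is_substance(self) -> bool:
        return self.version != 0

    @property
    def kind(self) -> str:
        return "substance" if self.is_substance else "compound"

    def encode(self) -> int:
        return encode_gid(self.structure_id, self.version, self.local_id)

    def hex(self) -> str:
        return gid_to_hex(self.encode())


def encode_gid(structure_id: int, version: int, local_id: int) -> int:
    """Pack (structure id, version, LID) into a 64-bit unsigned integer."""
    gid = GlobalConformerId(structure_id, version, local_id)  # range check
    return (gid.structure_id << 32) | (gid.version << 16) | gid.local_id


def decode_gid(gid: int) -> GlobalConformerId:
    """Unpack a 64-bit GID; inverse of :func:`encode_gid` on in-range input."""
    if not (0 <= gid <= 0xFFFFFFFFFFFFFFFF):
        raise ValueError("gid out of 64-bit range")
    return GlobalConformerId(
        structure_id=(gid >> 32) & _MASK32,
        version=(gid >> 16) & _MASK16,
        local_id=gid & _MASK16,
    )


def gid_to_hex(gid: int) -> str:
    """16-digit zero-padded hex rendering (case-insensitive on input)."""
    return format(gid, "016X")


def gid_from_hex(text: str) -> int:
    value = int(text.strip(), 16)
    if not (0 <= value <= 0xFFFFFFFFFFFFFFFF):
        raise ValueError("hex gid out of 64-bit range")
    return value
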