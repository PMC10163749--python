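"""Phonetic encoding of names.

Implements the Double Metaphone algorithm (L. Philips, 2000), which maps
names to short phonetic codes so that alternative spellings of the same
spoken name collide: RUDOLF and RUDOLPH both encode to RTLF, JONATHAN and
JONATHON to JN0N ('0' denoting the 'th' sound).  The *primary* code is the
one used as the fuzzy partial-match tier for names; the secondary code
(covering alternative, often Slavic/Germanic, pronunciations) is computed
but not used by the linkage engine.

The encoder expects input already standardized to uppercase ASCII letters
(see :func:`bayeslink.identifiers.standardize_name`); any non-alphabetic
characters are ignored.
"""

from __future__ import annotations

__all__ = ["double_metaphone", "metaphone"]

_VOWELS = frozenset("AEIOUY")


def _is_slavo_germanic(word: str) -> bool:
    return any(s in word for s in ("W", "K", "CZ", "WITZ"))


def double_metaphone(word: str, max_length: int = 4) -> tuple[str, str]:
    """Return (primary, secondary) Double Metaphone codes of ``word``.

    Codes are truncated to ``max_length`` characters (4 by default, as in
    the original algorithm).  An empty or non-alphabetic input yields the
    empty ("null") code, which is still a legitimate comparison token.
    """
    word = "".join(ch for ch in word.upper() if "A" <= ch <= "Z")
    if not word:
        return "", ""

    length = len(word)
    last = length - 1
    slavo = _is_slavo_germanic(word)
    primary: list[str] = []
    secondary: list[str] = []

    def char(i: int) -> str:
        return word[i] if 0 <= i < length else ""

    def substr(start: int, n: int) -> str:
        return word[max(start, 0):max(start, 0) + n] if start >= 0 else ""

    def match(start: int, n: int, *options: str) -> bool:
        return substr(start, n) in options

    def is_vowel(i: int) -> bool:
        return char(i) in _VOWELS

    def add(p: str, s: str | None = None) -> None:
        primary.append(p)
        secondary.append(p if s is None else s)

    pos = 0
    # Silent initial letters: GN-, KN-, PN-, WR-, PS-.
    if match(0, 2, "GN", "KN", "PN", "WR", "PS"):
        pos = 1
    # Initial X is pronounced Z (Xavier), which maps to S.
    if char(0) == "X":
        add("S")
        pos = 1

    while pos < length and (len(primary) < max_length or len(secondary) < max_length):
        c = char(pos)

        if c in _VOWELS:
            if pos == 0:  # all initial vowels map to A
                add("A")
            pos += 1
            continue

        if c == "B":
            add("P")
            pos += 2 if char(pos + 1) == "B" else 1
            continue

        if c == "C":
            # Various Germanic contexts: ACH but not MACHER-style.
            if (pos > 1 and not is_vowel(pos - 2) and match(pos - 1, 3, "ACH")
                    and char(pos + 2) != "I"
                    and (char(pos + 2) != "E" or match(pos - 2, 6, "BACHER", "MACHER"))):
                add("K")
                pos += 2
                continue
            if pos == 0 and match(0, 6, "CAESAR"):
                add("S")
                pos += 2
                continue
            if match(pos, 4, "CHIA"):  # italian e.g. CHIANTI
                add("K")
                pos += 2
                continue
            if match(pos, 2, "CH"):
                if pos > 0 and match(pos, 4, "CHAE"):  # e.g. MICHAEL
                    add("K", "X")
                    pos += 2
                    continue
                # Greek roots pronounced with K.
                if (pos == 0
                        and (match(1, 5, "HARAC", "HARIS")
                             or match(1, 3, "HOR", "HYM", "HIA", "HEM"))
                        and not match(0, 5, "CHORE")):
                    add("K")
                    pos += 2
                    continue
                if ((match(0, 4, "VAN ", "VON ") or match(0, 3, "SCH"))
                        or match(pos - 2, 6, "ORCHES", "ARCHIT", "ORCHID")
                        or char(pos + 2) in ("T", "S")
                        or ((char(pos - 1) in ("A", "O", "U", "E") or pos == 0)
                            and char(pos + 2) in ("L", "R", "N", "M", "B", "H", "F", "V", "W", " ", ""))):
                    add("K")
                else:
                    if pos > 0:
                        if match(0, 2, "MC"):
                            add("K")
                        else:
                            add("X", "K")
                    else:
                        add("X")
                pos += 2
                continue
            if match(pos, 2, "CZ") and not match(pos - 2, 4, "WICZ"):
                add("S", "X")
                pos += 2
                continue
            if match(pos + 1, 3, "CIA"):  # e.g. FOCACCIA
                add("X")
                pos += 3
                continue
            if match(pos, 2, "CC") and not (pos == 1 and char(0) == "M"):
                # double C, e.g. BELLOCCHIO / BACCHUS
                if char(pos + 2) in ("I", "E", "H") and not match(pos + 2, 2, "HU"):
                    if ((pos == 1 and char(0) == "A")
                            or match(pos - 1, 5, "UCCEE", "UCCES")):
                        add("KS")
                    else:
                        add("X")
                    pos += 3
                    continue
                add("K")
                pos += 2
                continue
            if match(pos, 2, "CK", "CG", "CQ"):
                add("K")
                pos += 2
                continue
            if match(pos, 2, "CI", "CE", "CY"):
                if match(pos, 3, "CIO", "CIE", "CIA"):
                    add("S", "X")
                else:
                    add("S")
                pos += 2
                continue
            add("K")
            if match(pos + 1, 2, " C", " Q", " G"):
                pos += 3
            elif char(pos + 1) in ("C", "K", "Q") and not match(pos + 1, 2, "CE", "CI"):
                pos += 2
            else:
                pos += 1
            continue

        if c == "D":
            if match(pos, 2, "DG"):
                if char(pos + 2) in ("I", "E", "Y"):  # e.g. EDGE
                    add("J")
                    pos += 3
                else:  # e.g. EDGAR
                    add("TK")
                    pos += 2
                continue
            add("T")
            pos += 2 if match(pos, 2, "DT", "DD") else 1
            continue

        if c == "F":
            add("F")
            pos += 2 if char(pos + 1) == "F" else 1
            continue

        if c == "G":
            if char(pos + 1) == "H":
                if pos > 0 and not is_vowel(pos - 1):
                    add("K")
                    pos += 2
                    continue
                if pos == 0:
                    if char(pos + 2) == "I":  # ghislane
                        add("J")
                    else:  # ghoul
                        add("K")
                    pos += 2
                    continue
                # GH silent in HUGH/BOUGH/etc. contexts
                if ((pos > 1 and char(pos - 2) in ("B", "H", "D"))
                        or (pos > 2 and char(pos - 3) in ("B", "H", "D"))
                        or (pos > 3 and char(pos - 4) in ("B", "H"))):
                    pos += 2
                    continue
                if pos > 2 and char(pos - 1) == "U" and char(pos - 3) in ("C", "G", "L", "R", "T"):
                    add("F")  # laugh, cough, rough
                elif pos > 0 and char(pos - 1) != "I":
                    add("K")
                pos += 2
                continue
            if char(pos + 1) == "N":
                if pos == 1 and is_vowel(0) and not slavo:
                    add("KN", "N")
                elif not match(pos + 2, 2, "EY") and char(pos + 1) != "Y" and not slavo:
                    add("N", "KN")
                else:
                    add("KN")
                pos += 2
                continue
            if match(pos + 1, 2, "LI") and not slavo:  # tagliaro
                add("KL", "L")
                pos += 2
                continue
            if pos == 0 and (char(pos + 1) == "Y"
                             or match(pos + 1, 2, "ES", "EP", "EB", "EL", "EY", "IB",
                                      "IL", "IN", "IE", "EI", "ER")):
                add("K", "J")
                pos += 2
                continue
            if ((match(pos + 1, 2, "ER") or char(pos + 1) == "Y")
                    and not match(0, 6, "DANGER", "RANGER", "MANGER")
                    and char(pos - 1) not in ("E", "I")
                    and not match(pos - 1, 3, "RGY", "OGY")):
                add("K", "J")
                pos += 2
                continue
            if (char(pos + 1) in ("E", "I", "Y")
                    or match(pos - 1, 4, "AGGI", "OGGI")):
                if (match(0, 4, "VAN ", "VON ") or match(0, 3, "SCH")
                        or match(pos + 1, 2, "ET")):
                    add("K")
                elif match(pos + 1, 4, "IER "):
                    add("J")
                else:
                    add("J", "K")
                pos += 2
                continue
            add("K")
            pos += 2 if char(pos + 1) == "G" else 1
            continue

        if c == "H":
            # keep H only between vowels or at the start before a vowel
            if (pos == 0 or is_vowel(pos - 1)) and is_vowel(pos + 1):
                add("H")
                pos += 2
            else:
                pos += 1
            continue

        if c == "J":
            if match(pos, 4, "JOSE") or match(0, 4, "SAN "):
                if (pos == 0 and char(pos + 4) == " ") or match(0, 4, "SAN "):
                    add("H")
                else:
                    add("J", "H")
                pos += 1
                continue
            if pos == 0 and not match(pos, 4, "JOSE"):
                add("J", "A")  # Yankelovich / Jankelowicz
            elif (is_vowel(pos - 1) and not slavo
                  and char(pos + 1) in ("A", "O")):
                add("J", "H")
            elif pos == last:
                add("J", "")
            elif (char(pos + 1) not in ("L", "T", "K", "S", "N", "M", "B", "Z")
                  and char(pos - 1) not in ("S", "K", "L")):
                add("J")
            pos += 2 if char(pos + 1) == "J" else 1
            continue

        if c == "K":
            add("K")
            pos += 2 if char(pos + 1) == "K" else 1
            continue

        if c == "L":
            if char(pos + 1) == "L":
                # spanish e.g. CABRILLO, GALLEGOS
                if ((pos == length - 3 and match(pos - 1, 4, "ILLO", "ILLA", "ALLE"))
                        or ((match(last - 1, 2, "AS", "OS") or char(last) in ("A", "O"))
                            and match(pos - 1, 4, "ALLE"))):
                    add("L", "")
                    pos += 2
                    continue
                pos += 2
            else:
                pos += 1
            add("L")
            continue

        if c == "M":
            if ((match(pos - 1, 3, "UMB")
                 and (pos + 1 == last or match(pos + 2, 2, "ER")))
                    or char(pos + 1) == "M"):
                pos += 2
            else:
                pos += 1
            add("M")
            continue

        if c == "N":
            add("N")
            pos += 2 if char(pos + 1) == "N" else 1
            continue

        if c == "P":
            if char(pos + 1) == "H":
                add("F")
                pos += 2
                continue
            add("P")
            pos += 2 if char(pos + 1) in ("P", "B") else 1
            continue

        if c == "Q":
            add("K")
            pos += 2 if char(pos + 1) == "Q" else 1
            continue

        if c == "R":
            # french e.g. ROGIER, but exclude HOCHMEIER
            if (pos == last and not slavo and match(pos - 2, 2, "IE")
                    and not match(pos - 4, 2, "ME", "MA")):
                add("", "R")
            else:
                add("R")
            pos += 2 if char(pos + 1) == "R" else 1
            continue

        if c == "S":
            if match(pos - 1, 3, "ISL", "YSL"):  # silent: island, isle
                pos += 1
                continue
            if pos == 0 and match(0, 5, "SUGAR"):
                add("X", "S")
                pos += 1
                continue
            if match(pos, 2, "SH"):
                if match(pos + 1, 4, "HEIM", "HOEK", "HOLM", "HOLZ"):
                    add("S")  # germanic
                else:
                    add("X")
                pos += 2
                continue
            if match(pos, 3, "SIO", "SIA") or match(pos, 4, "SIAN"):
                if slavo:
                    add("S")
                else:
                    add("S", "X")
                pos += 3
                continue
            if (pos == 0 and char(1) in ("M", "N", "L", "W")) or char(pos + 1) == "Z":
                add("S", "X")  # german/slavic SM-/SZ-
                pos += 2 if char(pos + 1) == "Z" else 1
                continue
            if match(pos, 2, "SC"):
                if char(pos + 2) == "H":
                    if match(pos + 3, 2, "OO", "ER", "EN", "UY", "ED", "EM"):
                        # dutch: SCHOOL, SCHOONER
                        if match(pos + 3, 2, "ER", "EN"):
                            add("X", "SK")
                        else:
                            add("SK")
                    else:
                        if pos == 0 and not is_vowel(3) and char(3) != "W":
                            add("X", "S")
                        else:
                            add("X")
                elif char(pos + 2) in ("I", "E", "Y"):
                    add("S")
                else:
                    add("SK")
                pos += 3
                continue
            if pos == last and match(pos - 2, 2, "AI", "OI"):
                add("", "S")  # french: RESNAIS, ARTOIS
            else:
                add("S")
            pos += 2 if char(pos + 1) in ("S", "Z") else 1
            continue

        if c == "T":
            if match(pos, 4, "TION") or match(pos, 3, "TIA", "TCH"):
                add("X")
                pos += 3
                continue
            if match(pos, 2, "TH") or match(pos, 3, "TTH"):
                if (match(pos + 2, 2, "OM", "AM")  # THOMAS, THAMES
                        or match(0, 4, "VAN ", "VON ") or match(0, 3, "SCH")):
                    add("T")
                else:
                    add("0", "T")
                pos += 2
                continue
            add("T")
            pos += 2 if char(pos + 1) in ("T", "D") else 1
            continue

        if c == "V":
            add("F")
            pos += 2 if char(pos + 1) == "V" else 1
            continue

        if c == "W":
            if match(pos, 2, "WR"):
                add("R")
                pos += 2
                continue
            if pos == 0 and (is_vowel(pos + 1) or match(pos, 2, "WH")):
                if is_vowel(pos + 1):
                    add("A", "F")  # Wasserman / Vasserman
                else:
                    add("A")  # Whitney (need Uomo to match)
            if ((pos == last and is_vowel(pos - 1))
                    or match(pos - 1, 5, "EWSKI", "EWSKY", "OWSKI", "OWSKY")
                    or match(0, 3, "SCH")):
                add("", "F")  # Arnow / Arnoff
                pos += 1
                continue
            if match(pos, 4, "WICZ", "WITZ"):
                add("TS", "FX")
                pos += 4
                continue
            pos += 1
            continue

        if c == "X":
            if not (pos == last
                    and (match(pos - 3, 3, "IAU", "EAU")
                         or match(pos - 2, 2, "AU", "OU"))):
                add("KS")  # not french
            pos += 2 if char(pos + 1) in ("C", "X") else 1
            continue

        if c == "Z":
            if char(pos + 1) == "H":  # chinese pinyin e.g. ZHAO
                add("J")
                pos += 2
                continue
            if (match(pos + 1, 2, "ZO", "ZI", "ZA")
                    or (slavo and pos > 0 and char(pos - 1) != "T")):
                add("S", "TS")
            else:
                add("S")
            pos += 2 if char(pos + 1) == "Z" else 1
            continue

        pos += 1  # any other character: skip

    return "".join(primary)[:max_length], "".join(secondary)[:max_length]


def metaphone(word: str, max_length: int = 4) -> str:
    """The primary Double Metaphone code — the partial-match tier for names."""
    return double_metaphone(word, max_length)[0]
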