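"""Mining the literature for microRNA function.

The pipeline takes pre-extracted full-text articles (abstract, introduction,
results and discussion sections, plus the list of organisms associated with
each article by an external tagger), splits them into sentences, recognizes
microRNA gene names, discards table/reference extracts, resolves species and
gene-family ambiguity, and scores each surviving sentence for functional
content.  Articles are then ranked per gene by the sum of their sentence
scores.

MicroRNA gene names have been standardized since 2002, so — unlike most
gene symbols — they can be recognized reliably with regular expressions:
``miR-#`` / ``miRNA-#`` / ``microRNA-#`` style numbered names plus a small
lexicon of exceptional names (let-7, lin-4, bantam, ...).
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Article",
    "Sentence",
    "MirnaMention",
    "FamilyTable",
    "ScoredSentence",
    "ArticleRank",
    "split_sentences",
    "find_mirna_names",
    "filter_sentences",
    "assign_species",
    "expand_family",
    "score_sentence",
    "rank_articles",
    "process_article",
    "mine_corpus",
    "read_corpus_jsonl",
    "load_stem_list",
    "load_species_lexicon",
    "default_positive_stems",
    "default_negative_stems",
    "default_species_lexicon",
    "default_family_table",
    "SECTIONS",
    "MAX_NAMES_PER_SENTENCE",
    "MAX_WORDS_PER_SENTENCE",
]

SECTIONS = ("abstract", "introduction", "results", "discussion")

# table/reference-extract filter thresholds: strictly more than these fails
MAX_NAMES_PER_SENTENCE = 25
MAX_WORDS_PER_SENTENCE = 200


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class MirnaMention:
    """One recognized microRNA gene name in a sentence.

    ``normalized`` is the canonical family-level key: prefix mapped to
    ``mir-``, lower-cased, arm suffix (-5p/-3p) stripped into ``arm``.
    """

    surface: str
    normalized: str
    span: tuple[int, int]
    arm: str | None = None


@dataclass
class Sentence:
    article_id: str
    text: str
    section: str = ""
    mentions: list[MirnaMention] = field(default_factory=list)

    @property
    def word_count(self) -> int:
        return len(self.text.split())

    @property
    def distinct_names(self) -> set[str]:
        return {m.normalized for m in self.mentions}


@dataclass
class Article:
    article_id: str
    sections: dict[str, str]
    species_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(self.sections.get(s, "").strip() for s in self.sections):
            raise ValueError(f"article {self.article_id}: all sections empty")


@dataclass
class ScoredSentence:
    sentence: Sentence
    score: int
    assigned: list[tuple[str, str]] = field(default_factory=list)  # (species, accession)


@dataclass(frozen=True)
class ArticleRank:
    article_id: str
    total_score: int
    n_sentences: int


class FamilyTable:
    """Maps (species, family-level name) to member gene accessions.

    Rows are (species_code, family_key, gene_name, gene_accession), unique
    on (species, family_key, gene_name).
    """

    def __init__(self, rows: Iterable[tuple[str, str, str, str]]):
        self.rows: list[tuple[str, str, str, str]] = []
        seen: set[tuple[str, str, str]] = set()
        self._by_species: dict[str, list[tuple[str, str, str]]] = {}
        for species, family_key, gene_name, accession in rows:
            key = (species, family_key, gene_name)
            if key in seen:
                raise ValueError(f"duplicate family-table row {key}")
            seen.add(key)
            self.rows.append((species, family_key, gene_name, accession))
            self._by_species.setdefault(species, []).append(
                (family_key, gene_name, accession)
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilyTable":
        rows = []
        with open(path) as handle:
            reader = csv.reader(
                (ln for ln in handle if not ln.startswith("#")), delimiter="\t"
            )
            header = next(reader)
            for row in reader:
                rows.append((row[0], row[1], row[2], row[3]))
        return cls(rows)

    def genes(self, species_code: str) -> list[tuple[str, str, str]]:
        return self._by_species.get(species_code, [])


# ---------------------------------------------------------------------------
# Packaged default lexicons


def load_stem_list(path: str | Path) -> list[str]:
    """Read a plain word-stem list, one per line, '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.lower())
    return out


def load_species_lexicon(path: str | Path) -> dict[str, list[str]]:
    """TSV: species_code <tab> pipe-separated names/abbreviations."""
    lexicon: dict[str, list[str]] = {}
    with open(path) as handle:
        reader = csv.reader(
            (ln for ln in handle if not ln.startswith("#")), delimiter="\t"
        )
        next(reader)  # header
        for code, names in reader:
            lexicon[code] = [n.strip() for n in names.split("|") if n.strip()]
    return lexicon


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mirqc.data").joinpath(name)))


def default_positive_stems() -> list[str]:
    return load_stem_list(_data_path("positive_keywords.txt"))


def default_negative_stems() -> list[str]:
    return load_stem_list(_data_path("negative_keywords.txt"))


def default_species_lexicon() -> dict[str, list[str]]:
    return load_species_lexicon(_data_path("species_lexicon.tsv"))


def default_family_table() -> FamilyTable:
    return FamilyTable.from_tsv(_data_path("family_table.synthetic.tsv"))


def _default_exceptional_names() -> list[tuple[str, bool]]:
    out = []
    for line in _data_path("exceptional_names.txt").read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            name, kind = line.split("\t")
            out.append((name.lower(), kind == "suffixed"))
    return out


# ---------------------------------------------------------------------------
# Sentence splitting

_ABBREVIATIONS = {
    "fig", "figs", "eq", "eqs", "ref", "refs", "no", "nos", "vs", "cf",
    "ca", "approx", "al", "e.g", "i.e", "etc", "dr", "prof", "st",
    "sp", "spp", "subsp", "var", "mol", "vol", "suppl",
}


# lower-case tokens that legitimately open a sentence (gene names)
_LOWER_SENTENCE_START_RE = re.compile(
    r"(?:miR-\d|mir-\d|let-7|lin-4|bantam|lsy-6|iab-[48])"
)


def split_sentences(section_text: str, article_id: str = "", section: str = "") -> list[Sentence]:
    """Deterministic sentence segmentation.

    Splits at '.', '!' or '?' followed by whitespace and a capital letter,
    digit, or lower-case microRNA gene name ("miR-21 targets ..."),
    protecting common abbreviations ("Fig.", "et al.", single initials) and
    decimal numbers (which have no whitespace after the dot and are
    therefore never candidates).
    """
    text = " ".join(section_text.split())
    sentences: list[str] = []
    start = 0
    for m in re.finditer(r"([.!?]+)(\s+)", text):
        nxt = m.end()
        if nxt >= len(text):
            break
        if not (
            text[nxt].isupper()
            or text[nxt].isdigit()
            or _LOWER_SENTENCE_START_RE.match(text, nxt)
        ):
            continue
        if m.group(1) == ".":
            prev = re.search(r"(\S+)$", text[: m.start(1)])
            word = prev.group(1).lower().lstrip("([\"'") if prev else ""
            if word in _ABBREVIATIONS or re.fullmatch(r"[a-z]", word):
                continue
        sentences.append(text[start : m.end(1)])
        start = nxt
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return [Sentence(article_id=article_id, text=s, section=section) for s in sentences]


# ---------------------------------------------------------------------------
# Name recognition

# real-world typography: unicode hyphen/dash variants normalized before matching
_HYPHENS_RE = re.compile("[‐‑‒–—−]")

_SEP = r"[-\s]"
_SUFFIX = r"(?P<letter>[a-z])?(?:-(?P<copy>\d+)(?!\d*p))?(?:-(?P<arm>[35]p))?"

_NUMBERED_RE = re.compile(
    r"(?<![A-Za-z0-9])"
    r"(?:microRNA|miRNA|miR)" + _SEP + r"?(?P<num>\d+)" + _SUFFIX +
    r"(?![A-Za-z0-9])",
    re.IGNORECASE,
)


def _exceptional_patterns(
    names: Sequence[tuple[str, bool]]
) -> list[tuple[re.Pattern[str], str]]:
    patterns = []
    for name, suffixed in names:
        body = re.escape(name).replace(r"\-", _SEP + "?")
        pat = r"(?<![A-Za-z0-9])" + body
        if suffixed:
            pat += _SUFFIX
        else:
            pat += r"(?:-(?P<arm>[35]p))?"
        pat += r"(?![A-Za-z0-9])"
        patterns.append((re.compile(pat, re.IGNORECASE), name))
    return patterns


_DEFAULT_EXCEPTIONAL = None


def find_mirna_names(
    sentence_text: str,
    exceptional_names: Sequence[tuple[str, bool]] | None = None,
) -> list[MirnaMention]:
    """Recognize microRNA gene names case-insensitively.

    Numbered names (miR-21, miRNA-21, microRNA-21, microRNA 21, mir-133a-2,
    miR-499a-5p ...) are matched by pattern; exceptional names come from a
    configurable lexicon (default: let-7, lin-4, bantam, lsy-6, iab-4,
    iab-8, the first two with optional letter/copy suffixes).  Overlapping
    matches are resolved leftmost-longest.  Bare prefixes with no gene
    number ("2 miR and 3 microRNAs") are not mentions.
    """
    global _DEFAULT_EXCEPTIONAL
    if exceptional_names is None:
        if _DEFAULT_EXCEPTIONAL is None:
            _DEFAULT_EXCEPTIONAL = _default_exceptional_names()
        exceptional_names = _DEFAULT_EXCEPTIONAL

    text = _HYPHENS_RE.sub("-", sentence_text)
    candidates: list[tuple[int, int, MirnaMention]] = []

    for m in _NUMBERED_RE.finditer(text):
        normalized = "mir-" + m.group("num")
        if m.group("letter"):
            normalized += m.group("letter").lower()
        if m.group("copy"):
            normalized += "-" + m.group("copy")
        candidates.append(
            (
                m.start(),
                m.end(),
                MirnaMention(
                    surface=sentence_text[m.start() : m.end()],
                    normalized=normalized,
                    span=(m.start(), m.end()),
                    arm=m.group("arm").lower() if m.group("arm") else None,
                ),
            )
        )
    for pattern, name in _exceptional_patterns(exceptional_names):
        for m in pattern.finditer(text):
            normalized = name
            groups = m.groupdict()
            if groups.get("letter"):
                normalized += groups["letter"].lower()
            if groups.get("copy"):
                normalized += "-" + groups["copy"]
            arm = groups.get("arm")
            candidates.append(
                (
                    m.start(),
                    m.end(),
                    MirnaMention(
                        surface=sentence_text[m.start() : m.end()],
                        normalized=normalized,
                        span=(m.start(), m.end()),
                        arm=arm.lower() if arm else None,
                    ),
                )
            )

    # leftmost-longest, non-overlapping
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    mentions: list[MirnaMention] = []
    last_end = -1
    for start, end, mention in candidates:
        if start >= last_end:
            mentions.append(mention)
            last_end = end
    return mentions


# ---------------------------------------------------------------------------
# Filtering, species assignment, family expansion, scoring


def filter_sentences(
    sentences: Sequence[Sentence],
    max_names: int = MAX_NAMES_PER_SENTENCE,
    max_words: int = MAX_WORDS_PER_SENTENCE,
) -> tuple[list[Sentence], list[Sentence]]:
    """Separate real prose from table/reference extracts.

    A sentence is eliminated iff it carries strictly more than ``max_names``
    distinct normalized microRNA names or strictly more than ``max_words``
    whitespace tokens; kept and eliminated partition the input in order.
    """
    kept, eliminated = [], []
    for s in sentences:
        if len(s.distinct_names) > max_names or s.word_count > max_words:
            eliminated.append(s)
        else:
            kept.append(s)
    return kept, eliminated


def _species_named_in(text: str, names: Sequence[str]) -> bool:
    low = text.lower()
    for name in names:
        if re.search(
            r"(?<![A-Za-z])" + re.escape(name.lower()) + r"(?![A-Za-z])", low
        ):
            return True
    return False


def assign_species(
    sentence: Sentence | str,
    article_species_list: Sequence[str],
    species_lexicon: Mapping[str, Sequence[str]],
) -> list[str]:
    """Decide which of the article's species a sentence refers to.

    If the sentence explicitly names some of the article's species, only
    those are assigned; if it names none of them, the microRNA mention
    cannot be localized and all article species are assigned.  Names of
    species absent from the article's list do not veto on their own.
    """
    if not article_species_list:
        warnings.warn("article has no associated species; nothing to assign")
        return []
    text = sentence.text if isinstance(sentence, Sentence) else sentence
    named = [
        code
        for code in article_species_list
        if _species_named_in(text, species_lexicon.get(code, []))
    ]
    return sorted(named) if named else sorted(set(article_species_list))


_REMAINDER_RE = re.compile(r"([a-z])?(-\d+)?$")


def expand_family(
    mention: MirnaMention | str,
    species_code: str,
    family_table: FamilyTable,
) -> list[str]:
    """Expand a (possibly family-level) name to member gene accessions.

    A bare family name ("let-7") expands to every member in the species; a
    lettered name ("let-7a") to that letter group (let-7a-1..3); a fully
    specified name ("mir-133a-2") to exactly that gene.  Matching is by
    name: a gene matches when its name minus the mention is empty, a single
    letter, a copy number, or a letter plus copy number — so "mir-21" never
    swallows mir-214.  Unknown names yield an empty list.
    """
    name = mention.normalized if isinstance(mention, MirnaMention) else mention.lower()
    hits = []
    for _family, gene_name, accession in family_table.genes(species_code):
        if gene_name == name or (
            gene_name.startswith(name)
            and _REMAINDER_RE.fullmatch(gene_name[len(name):]) is not None
        ):
            hits.append(accession)
    return sorted(set(hits))


_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def score_sentence(
    sentence: Sentence | str,
    positive_lexicon: Sequence[str],
    negative_lexicon: Sequence[str],
) -> int:
    """Functional-content score: positive-stem hits minus negative-stem hits.

    Stems are matched case-insensitively as word prefixes ("regulat" hits
    regulates/regulation); each token contributes at most one hit per
    lexicon, and every hitting token counts.
    """
    text = (sentence.text if isinstance(sentence, Sentence) else sentence).lower()
    tokens = _TOKEN_RE.findall(text)
    pos = sum(1 for t in tokens if any(t.startswith(stem) for stem in positive_lexicon))
    neg = sum(1 for t in tokens if any(t.startswith(stem) for stem in negative_lexicon))
    return pos - neg


def rank_articles(
    scored_sentences: Iterable[ScoredSentence],
) -> dict[str, list[ArticleRank]]:
    """Rank each gene's articles by summed sentence score.

    Ties break by sentence count (descending) then article id (ascending)
    so the ordering is deterministic.
    """
    sums: dict[tuple[str, str], int] = {}
    counts: dict[tuple[str, str], int] = {}
    for ss in scored_sentences:
        for _species, accession in set(ss.assigned):
            key = (accession, ss.sentence.article_id)
            sums[key] = sums.get(key, 0) + ss.score
            counts[key] = counts.get(key, 0) + 1
    per_gene: dict[str, list[ArticleRank]] = {}
    for (accession, article_id), total in sums.items():
        per_gene.setdefault(accession, []).append(
            ArticleRank(article_id, total, counts[(accession, article_id)])
        )
    for accession, ranks in per_gene.items():
        ranks.sort(key=lambda r: (-r.total_score, -r.n_sentences, r.article_id))
    return dict(sorted(per_gene.items()))


# ---------------------------------------------------------------------------
# Pipeline


def process_article(
    article: Article,
    family_table: FamilyTable | None = None,
    species_lexicon: Mapping[str, Sequence[str]] | None = None,
    positive_stems: Sequence[str] | None = None,
    negative_stems: Sequence[str] | None = None,
    max_names: int = MAX_NAMES_PER_SENTENCE,
    max_words: int = MAX_WORDS_PER_SENTENCE,
) -> list[ScoredSentence]:
    """Run the full per-article pipeline; returns scored, assigned sentences.

    Only sentences that mention at least one microRNA name, survive the
    table/reference filter, and expand to at least one gene in the family
    table are returned.
    """
    family_table = family_table if family_table is not None else default_family_table()
    species_lexicon = (
        species_lexicon if species_lexicon is not None else default_species_lexicon()
    )
    positive_stems = (
        positive_stems if positive_stems is not None else default_positive_stems()
    )
    negative_stems = (
        negative_stems if negative_stems is not None else default_negative_stems()
    )

    sentences: list[Sentence] = []
    for section in SECTIONS:
        text = article.sections.get(section, "")
        if text.strip():
            sentences.extend(split_sentences(text, article.article_id, section))
    for s in sentences:
        s.mentions = find_mirna_names(s.text)
    with_names = [s for s in sentences if s.mentions]
    kept, _eliminated = filter_sentences(with_names, max_names, max_words)

    out: list[ScoredSentence] = []
    for s in kept:
        species = assign_species(s, article.species_list, species_lexicon)
        assigned: list[tuple[str, str]] = []
        for mention in s.mentions:
            for code in species:
                for accession in expand_family(mention, code, family_table):
                    if (code, accession) not in assigned:
                        assigned.append((code, accession))
        if not assigned:
            continue
        score = score_sentence(s, positive_stems, negative_stems)
        out.append(ScoredSentence(sentence=s, score=score, assigned=assigned))
    return out


@dataclass
class MiningResult:
    sentences: list[ScoredSentence]
    rankings: dict[str, list[ArticleRank]]

    def write_sentences_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene_accession", "species_code", "article_id", "score", "text"])
            for ss in self.sentences:
                for code, accession in ss.assigned:
                    writer.writerow(
                        [accession, code, ss.sentence.article_id, ss.score, ss.sentence.text]
                    )

    def write_rankings_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene_accession", "rank", "article_id", "total_score", "n_sentences"])
            for accession, ranks in self.rankings.items():
                for i, r in enumerate(ranks, start=1):
                    writer.writerow([accession, i, r.article_id, r.total_score, r.n_sentences])


def mine_corpus(articles: Iterable[Article], **kwargs) -> MiningResult:
    """Process a whole corpus and rank articles per gene."""
    scored: list[ScoredSentence] = []
    for article in articles:
        scored.extend(process_article(article, **kwargs))
    return MiningResult(sentences=scored, rankings=rank_articles(scored))


def read_corpus_jsonl(path: str | Path) -> list[Article]:
    """One JSON record per line: {"id": ..., "sections": {...}, "species": [...]}."""
    articles = []
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            obj = json.loads(line)
            articles.append(
                Article(
                    article_id=str(obj["id"]),
                    sections={k: str(v) for k, v in obj.get("sections", {}).items()},
                    species_list=[str(s) for s in obj.get("species", [])],
                )
            )
    return articles
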