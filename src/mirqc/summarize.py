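"""Word-cloud term frequencies for a gene's associated sentences.

The word cloud itself is presentation; the tested contract here is the
term-frequency table it is drawn from.  Tokens are lower-cased alphanumeric
(hyphens allowed inside); English stop words, curated scientific terms,
pure numbers and tokens shorter than three characters are removed before
counting.  Clouds are only shown for genes with at least ten associated
sentences — below that the summary is too noisy to be useful.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .litmine import ScoredSentence, Sentence, load_stem_list

__all__ = [
    "TermFrequencyTable",
    "term_frequencies",
    "wordcloud_eligible",
    "write_term_frequencies_tsv",
    "render_wordcloud_png",
    "default_english_stopwords",
    "default_curated_stoplist",
    "MIN_SENTENCES_FOR_CLOUD",
]

MIN_SENTENCES_FOR_CLOUD = 10

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")
_NUMERIC_RE = re.compile(r"[\d-]+$")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mirqc.data").joinpath(name)))


def default_english_stopwords() -> frozenset[str]:
    return frozenset(load_stem_list(_data_path("english_stopwords.txt")))


def default_curated_stoplist() -> frozenset[str]:
    return frozenset(load_stem_list(_data_path("curated_stopwords.txt")))


@dataclass
class TermFrequencyTable:
    """Token counts over a gene's retained sentences."""

    gene_accession: str
    terms: dict[str, int] = field(default_factory=dict)
    n_sentences: int = 0

    def top(self, n: int = 20) -> list[tuple[str, int]]:
        return sorted(self.terms.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


def term_frequencies(
    sentences: Sequence[Sentence | ScoredSentence | str],
    english_stopwords: frozenset[str] | None = None,
    curated_stoplist: frozenset[str] | None = None,
    gene_accession: str = "",
    min_token_length: int = 3,
) -> TermFrequencyTable:
    """Count retained tokens across a gene's sentences.

    Dropped: tokens in either stop list, pure numbers, and tokens shorter
    than ``min_token_length`` characters.  The count is linear in the input:
    duplicated sentences double their tokens' counts.
    """
    stops = (
        english_stopwords if english_stopwords is not None else default_english_stopwords()
    )
    curated = (
        curated_stoplist if curated_stoplist is not None else default_curated_stoplist()
    )
    table = TermFrequencyTable(gene_accession=gene_accession)
    for item in sentences:
        if isinstance(item, ScoredSentence):
            text = item.sentence.text
        elif isinstance(item, Sentence):
            text = item.text
        else:
            text = item
        table.n_sentences += 1
        for token in _TOKEN_RE.findall(text.lower()):
            if len(token) < min_token_length:
                continue
            if _NUMERIC_RE.fullmatch(token):
                continue
            if token in stops or token in curated:
                continue
            table.terms[token] = table.terms.get(token, 0) + 1
    return table


def wordcloud_eligible(
    table: TermFrequencyTable, min_sentences: int = MIN_SENTENCES_FOR_CLOUD
) -> bool:
    """True iff the gene has at least ``min_sentences`` associated sentences."""
    return table.n_sentences >= min_sentences


def write_term_frequencies_tsv(
    tables: Iterable[TermFrequencyTable], path: str | Path
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_accession", "term", "count", "n_sentences"])
        for table in tables:
            for term, count in sorted(table.terms.items(), key=lambda kv: (-kv[1], kv[0])):
                writer.writerow([table.gene_accession, term, count, table.n_sentences])


def render_wordcloud_png(
    table: TermFrequencyTable, path: str | Path, max_terms: int = 60
) -> None:
    """Optional, minimal cloud rendering via matplotlib (size ∝ frequency).

    Layout is a deterministic spiral; aesthetics are out of scope — the
    frequency table is the product, this is a convenience view.
    """
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = table.top(max_terms)
    if not top:
        raise ValueError("empty term table; nothing to render")
    max_count = top[0][1]
    fig, ax = plt.subplots(figsize=(8, 5))
    for i, (term, count) in enumerate(top):
        r = 0.05 + 0.45 * i / max(1, len(top) - 1)
        theta = 2.39996 * i  # golden-angle spiral
        x, y = 0.5 + r * math.cos(theta), 0.5 + r * math.sin(theta)
        ax.text(
            x, y, term,
            fontsize=8 + 22 * count / max_count,
            ha="center", va="center",
            transform=ax.transAxes,
        )
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
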