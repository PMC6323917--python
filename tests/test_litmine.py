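"""Name recognition, sentence filtering, species/family assignment, scoring."""

import random
import re

import pytest

from mirqc import litmine as lm


# ---------------------------------------------------------------------------
# Sentence splitting


def test_split_two_simple_sentences():
    got = lm.split_sentences("MiR-21 is overexpressed. It targets PTEN.")
    assert [s.text for s in got] == ["MiR-21 is overexpressed.", "It targets PTEN."]


def test_split_protects_abbreviations_and_decimals():
    text = "Expression rose 3.5-fold (Fig. 2A) in tumors. See also ref. 12. Dr. Smith et al. disagreed."
    got = [s.text for s in lm.split_sentences(text)]
    assert got == [
        "Expression rose 3.5-fold (Fig. 2A) in tumors.",
        "See also ref. 12.",
        "Dr. Smith et al. disagreed.",
    ]


def test_split_recovers_known_boundaries():
    """Generator ground truth: join synthetic sentences, recover them exactly."""
    rng = random.Random(41)
    words = ["expression", "tumor", "pathway", "binding", "decreased", "notably"]
    originals = []
    for _ in range(50):
        n = rng.randint(3, 12)
        body = [rng.choice(words) for _ in range(n)]
        body[0] = body[0].capitalize()
        originals.append(" ".join(body) + rng.choice([".", "?", "!"]))
    recovered = [s.text for s in lm.split_sentences(" ".join(originals))]
    assert recovered == originals


def test_split_allows_lowercase_gene_name_sentence_start():
    got = [s.text for s in lm.split_sentences("Tumors grew. miR-21 targets PTEN.")]
    assert got == ["Tumors grew.", "miR-21 targets PTEN."]


def test_sentence_word_count_is_whitespace_tokens():
    (s,) = lm.split_sentences("miR-21 targets  PTEN.")
    assert s.word_count == 3


# ---------------------------------------------------------------------------
# Name recognition

PUBLISHED_NAME_FORMS = [
    ("MicroRNA-21", "mir-21"),
    ("miR-21", "mir-21"),
    ("Mir-21", "mir-21"),
    ("MiR-21", "mir-21"),
    ("miRNA-21", "mir-21"),
    ("microRNA 21", "mir-21"),
    ("let-7a-1", "let-7a-1"),
    ("let-7a-2", "let-7a-2"),
    ("let-7a-3", "let-7a-3"),
    ("let-7", "let-7"),
    ("mir-214", "mir-214"),
    ("mir-221", "mir-221"),
    ("mir-222", "mir-222"),
    ("mir-328", "mir-328"),
    ("mir-451a", "mir-451a"),
    ("mir-451b", "mir-451b"),
    ("mir-181b-1", "mir-181b-1"),
    ("mir-181b-2", "mir-181b-2"),
    ("mir-29b-1", "mir-29b-1"),
    ("mir-29b-2", "mir-29b-2"),
    ("mir-34a", "mir-34a"),
    ("mir-9718", "mir-9718"),
    ("mir-16-1", "mir-16-1"),
    ("mir-16-2", "mir-16-2"),
    ("mir-29a", "mir-29a"),
    ("mir-27b", "mir-27b"),
    ("mir-130a", "mir-130a"),
    ("mir-126", "mir-126"),
    ("mir-296", "mir-296"),
    ("mir-378", "mir-378"),
    ("mir-19a", "mir-19a"),
    ("mir-23b", "mir-23b"),
    ("mir-26a-1", "mir-26a-1"),
    ("mir-26a-2", "mir-26a-2"),
    ("mir-122", "mir-122"),
    ("mir-133a-2", "mir-133a-2"),
    ("bantam", "bantam"),
    ("lin-4", "lin-4"),
]


@pytest.mark.parametrize("surface,normalized", PUBLISHED_NAME_FORMS)
def test_recognizes_published_name_forms(surface, normalized):
    """Every name form seen in the wild resolves to its canonical key."""
    sentence = f"Here {surface} is mentioned in running text."
    mentions = lm.find_mirna_names(sentence)
    assert [m.normalized for m in mentions] == [normalized]
    assert mentions[0].surface == surface


def test_torc1_sentence_single_mention():
    mentions = lm.find_mirna_names("MicroRNA-21 governs TORC1 activation")
    assert len(mentions) == 1 and mentions[0].normalized == "mir-21"


def test_cooperating_pair_detected():
    mentions = lm.find_mirna_names("let-7a and miR-214 cooperate")
    assert {m.normalized for m in mentions} == {"let-7a", "mir-214"}


def test_bare_prefixes_without_numbers_are_not_mentions():
    assert lm.find_mirna_names("2 miR and 3 microRNAs were studied") == []


def test_arm_suffix_stripped_into_field():
    (m,) = lm.find_mirna_names("miR-499a-5p binds SOX6")
    assert m.normalized == "mir-499a" and m.arm == "5p"


def test_unicode_hyphen_and_space_variants():
    for text in ["miR‐21 rose", "miR–21 rose", "miR 21 rose"]:
        (m,) = lm.find_mirna_names(text)
        assert m.normalized == "mir-21"


def test_span_indexes_into_sentence():
    text = "We found miR-133a-2 upregulated."
    (m,) = lm.find_mirna_names(text)
    assert text[m.span[0] : m.span[1]] == m.surface == "miR-133a-2"


def test_embedded_in_identifier_not_matched():
    assert lm.find_mirna_names("gene XmiR-21b3 and premiR21") == []


# ---------------------------------------------------------------------------
# Filtering


def _sentence(text):
    s = lm.Sentence(article_id="A1", text=text)
    s.mentions = lm.find_mirna_names(text)
    return s


def test_sentence_with_26_distinct_names_eliminated():
    names = " and ".join(f"miR-{i}" for i in range(1, 27))
    kept, eliminated = lm.filter_sentences([_sentence(f"{names} were listed.")])
    assert kept == [] and len(eliminated) == 1


def test_sentence_with_25_distinct_names_kept():
    names = " and ".join(f"miR-{i}" for i in range(1, 26))
    kept, eliminated = lm.filter_sentences([_sentence(f"{names} were listed.")])
    assert len(kept) == 1 and eliminated == []


def test_word_count_boundary_inclusive_at_200():
    filler = " ".join(["word"] * 197)
    exactly_200 = _sentence(f"miR-21 regulates things {filler}"[: None])
    assert exactly_200.word_count == 200
    over_200 = _sentence(f"miR-21 regulates some things {filler}")
    assert over_200.word_count == 201
    kept, eliminated = lm.filter_sentences([exactly_200, over_200])
    assert kept == [exactly_200] and eliminated == [over_200]


def test_filter_partitions_in_order():
    rng = random.Random(7)
    sentences = []
    for i in range(30):
        n_names = rng.choice([1, 5, 30])
        names = " ".join(f"miR-{j}" for j in range(1, n_names + 1))
        sentences.append(_sentence(f"Sentence {i}: {names}."))
    kept, eliminated = lm.filter_sentences(sentences)
    assert sorted(map(id, kept + eliminated)) == sorted(map(id, sentences))
    # order preserved within each partition
    pos = {id(s): i for i, s in enumerate(sentences)}
    assert [pos[id(s)] for s in kept] == sorted(pos[id(s)] for s in kept)
    assert [pos[id(s)] for s in eliminated] == sorted(pos[id(s)] for s in eliminated)
    # idempotent
    assert lm.filter_sentences(kept) == (kept, [])


# ---------------------------------------------------------------------------
# Species assignment


def test_named_subset_restricts_assignment(species_lexicon):
    got = lm.assign_species("In mouse liver, miR-122 dropped.", ["hsa", "mmu"], species_lexicon)
    assert got == ["mmu"]


def test_no_species_named_assigns_all(species_lexicon):
    got = lm.assign_species("miR-21 was upregulated.", ["hsa", "mmu"], species_lexicon)
    assert got == ["hsa", "mmu"]


def test_single_species_article(species_lexicon):
    got = lm.assign_species("In human samples, miR-21 rose.", ["hsa"], species_lexicon)
    assert got == ["hsa"]


def test_foreign_species_alone_does_not_veto(species_lexicon):
    got = lm.assign_species("Unlike in zebrafish, miR-21 rose.", ["hsa", "mmu"], species_lexicon)
    assert got == ["hsa", "mmu"]


def test_listed_species_wins_over_foreign(species_lexicon):
    got = lm.assign_species(
        "In human but not zebrafish, miR-21 rose.", ["hsa", "mmu"], species_lexicon
    )
    assert got == ["hsa"]


def test_empty_article_species_list_warns(species_lexicon):
    with pytest.warns(UserWarning):
        assert lm.assign_species("miR-21 rose.", [], species_lexicon) == []


# ---------------------------------------------------------------------------
# Family expansion


def test_let7_expands_to_all_eleven_human_members(family_table):
    accessions = lm.expand_family("let-7", "hsa", family_table)
    assert len(accessions) == 11


def test_fully_specified_gene_expands_to_itself(family_table):
    assert lm.expand_family("mir-133a-2", "hsa", family_table) == ["MI0000451"]


def test_letter_group_expands_to_copies(family_table):
    assert lm.expand_family("let-7a", "hsa", family_table) == [
        "MI0000060", "MI0000061", "MI0000062",
    ]


def test_name_prefix_never_swallows_longer_numbers(family_table):
    assert lm.expand_family("mir-21", "hsa", family_table) == ["MI0000077"]
    assert "MI0000290" in lm.expand_family("mir-214", "hsa", family_table)


def test_unknown_name_or_species_empty(family_table):
    assert lm.expand_family("mir-99999", "hsa", family_table) == []
    assert lm.expand_family("let-7", "xyz", family_table) == []


def test_expansion_matches_brute_force_table_scan(family_table):
    """Oracle: re-derive membership by scanning every row with the remainder rule."""
    remainder = re.compile(r"([a-z])?(-\d+)?$")
    queries = ["let-7", "let-7a", "mir-29", "mir-29b", "mir-16", "mir-133a", "bantam"]
    for species in ("hsa", "dme", "cel"):
        for q in queries:
            expected = sorted(
                {
                    acc
                    for sp, _fam, gene, acc in family_table.rows
                    if sp == species
                    and gene.startswith(q)
                    and remainder.fullmatch(gene[len(q):])
                }
            )
            assert lm.expand_family(q, species, family_table) == expected


# ---------------------------------------------------------------------------
# Scoring and ranking


def test_score_counts_lexicon_hits(positive_stems, negative_stems):
    s = "miR-21 targets PTEN and regulates proliferation"
    # independent recount against the shipped stem lists
    tokens = re.findall(r"[a-z0-9]+(?:-[a-z0-9]+)*", s.lower())
    expected = sum(
        1 for t in tokens if any(t.startswith(p) for p in positive_stems)
    ) - sum(1 for t in tokens if any(t.startswith(n) for n in negative_stems))
    assert lm.score_sentence(s, positive_stems, negative_stems) == expected == 3


def test_score_zero_without_lexicon_words(positive_stems, negative_stems):
    assert lm.score_sentence("miR-21 was seen here", positive_stems, negative_stems) == 0


def test_negative_stems_subtract(positive_stems, negative_stems):
    s = "Expression was measured by qPCR and normalized"
    assert lm.score_sentence(s, positive_stems, negative_stems) == 1 - 3


def test_score_additivity(positive_stems, negative_stems):
    a = "miR-21 targets PTEN"
    b = "levels were measured by qPCR"
    assert lm.score_sentence(f"{a} {b}", positive_stems, negative_stems) == (
        lm.score_sentence(a, positive_stems, negative_stems)
        + lm.score_sentence(b, positive_stems, negative_stems)
    )


def _scored(article_id, gene, score):
    s = lm.Sentence(article_id=article_id, text="x")
    return lm.ScoredSentence(sentence=s, score=score, assigned=[("hsa", gene)])


def test_rank_articles_by_summed_score():
    ranks = lm.rank_articles(
        [_scored("A", "G1", 4), _scored("A", "G1", 6), _scored("B", "G1", 7)]
    )
    assert [r.article_id for r in ranks["G1"]] == ["A", "B"]
    assert [r.total_score for r in ranks["G1"]] == [10, 7]


def test_rank_tie_broken_by_sentence_count_then_id():
    items = [_scored("B", "G1", 5), _scored("A", "G1", 2), _scored("A", "G1", 2), _scored("A", "G1", 1)]
    ranks = lm.rank_articles(items)
    assert [(r.article_id, r.total_score, r.n_sentences) for r in ranks["G1"]] == [
        ("A", 5, 3), ("B", 5, 1),
    ]
    same = lm.rank_articles([_scored("B", "G1", 5), _scored("A", "G1", 5)])
    assert [r.article_id for r in same["G1"]] == ["A", "B"]


def test_rank_matches_brute_force_on_random_corpus():
    rng = random.Random(53)
    items = []
    for _ in range(200):
        items.append(
            _scored(f"P{rng.randint(1, 8)}", f"G{rng.randint(1, 5)}", rng.randint(-3, 6))
        )
    ranks = lm.rank_articles(items)
    # independent re-aggregation
    sums, counts = {}, {}
    for it in items:
        key = (it.assigned[0][1], it.sentence.article_id)
        sums[key] = sums.get(key, 0) + it.score
        counts[key] = counts.get(key, 0) + 1
    for gene, ordered in ranks.items():
        expected = sorted(
            (
                (article, total, counts[(gene, article)])
                for (g, article), total in sums.items()
                if g == gene
            ),
            key=lambda t: (-t[1], -t[2], t[0]),
        )
        assert [(r.article_id, r.total_score, r.n_sentences) for r in ordered] == expected


# ---------------------------------------------------------------------------
# End-to-end pipeline


def _toy_article():
    return lm.Article(
        article_id="12345",
        sections={
            "abstract": (
                "MicroRNA-21 governs tumor growth. In mouse models, miR-21 "
                "inhibits PTEN expression. Levels were measured by qPCR."
            ),
            "results": "let-7 represses RAS in human cells.",
        },
        species_list=["hsa", "mmu"],
    )


def test_process_article_assigns_and_scores():
    scored = lm.process_article(_toy_article())
    by_text = {ss.sentence.text: ss for ss in scored}
    # species restricted where "mouse" is named
    mouse = by_text["In mouse models, miR-21 inhibits PTEN expression."]
    assert all(code == "mmu" for code, _ in mouse.assigned)
    # let-7 sentence names "human": hsa only, expanded to the 11 members
    let7 = by_text["let-7 represses RAS in human cells."]
    assert len(let7.assigned) == 11
    assert all(code == "hsa" for code, _ in let7.assigned)
    # sentence without species names assigns both article species
    first = by_text["MicroRNA-21 governs tumor growth."]
    assert {code for code, _ in first.assigned} == {"hsa", "mmu"}


def test_pipeline_deterministic_byte_identical(tmp_path):
    outs = []
    for i in range(2):
        result = lm.mine_corpus([_toy_article()])
        s_path = tmp_path / f"s{i}.tsv"
        r_path = tmp_path / f"r{i}.tsv"
        result.write_sentences_tsv(s_path)
        result.write_rankings_tsv(r_path)
        outs.append((s_path.read_bytes(), r_path.read_bytes()))
    assert outs[0] == outs[1]


def test_corpus_jsonl_roundtrip(tmp_path):
    path = tmp_path / "corpus.jsonl"
    path.write_text(
        '{"id": "1", "sections": {"abstract": "miR-21 regulates apoptosis."}, "species": ["hsa"]}\n'
    )
    (article,) = lm.read_corpus_jsonl(path)
    assert article.article_id == "1"
    result = lm.mine_corpus([article])
    assert len(result.sentences) == 1
    assert result.sentences[0].assigned == [("hsa", "MI0000077")]
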