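# Full pipeline configuration with every setting at its default.
# Any key omitted from a config file keeps the value shown here.

workdir: work
# input: posts.jsonl        # raw corpus; when unset, workdir/posts.jsonl
                            # (e.g. from the simulate stage) is used

cleaning:
  spam_terms: [vuzafestivalz]   # single-token bodies to drop
  # placeholder_patterns default to:
  #   "[removed]", "[deleted]", "Message withdrawn at poster's request."

bigram:
  min_count: 5          # pairs seen fewer times are never merged
  threshold: 10.0       # collocation score cutoff

dictionary:
  min_collection_count: 50   # drop words with fewer total occurrences
  max_doc_fraction: 0.5      # drop words in more than half of all posts

training:
  n_topics: null        # null: use the coherence scan's selection
  passes: 20
  chunksize: 1000
  decay: 0.5
  offset: 64
  iterations: 1000
  gamma_threshold: 0.001
  seed: 0
  # alpha and eta are symmetric 1/n_topics

coherence:
  window_size: 110      # boolean sliding-window width
  top_n_words: 20       # words per topic entering C_v

scan:
  k_min: 2
  k_max: 34
  repeats: 10           # random restarts per candidate K
  base_seed: 0

assignment:
  threshold: 0.75       # strict: a post at exactly 0.75 stays unassigned

labeling:
  n_words: 4
  form: literal         # a = log(phi) + log(phi)/P; or "relevance" for
                        # a = log(phi) + log(phi/P)

validation:
  sample_n: 50          # posts sampled per topic for human coding
  min_count: 3          # concern retention threshold within a sample
  seed: 0
  coded_csv: null       # completed coding sheet; enables coding summaries

synthetic: {}           # see SyntheticSpec for the generator defaults
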