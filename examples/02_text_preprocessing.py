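"""Clean, segment, and encode a bilingual subjective note.

The cleaning rules keep only Chinese characters and lowercase English
(numerals deleted, punctuation replaced by spaces); CJK runs are then
segmented by greedy longest-match against a lexicon, and the token
sequence becomes a fixed-length vector of vocabulary indices with
trailing zero padding.
"""

from notecode import build_vocabulary, clean_text, encode_pad, segment

note = "Fever up to 38 °C was noted. 頭痛3天, dizzy and intermittent tachypnea!"
lexicon = {"頭痛"}

cleaned = clean_text(note)
print("cleaned :", cleaned)
tokens = segment(cleaned, lexicon)
print("tokens  :", tokens)

vocab = build_vocabulary([tokens])
vec = encode_pad(tokens, vocab, max_len=12)
print("indices :", vec.indices.tolist())
print(f"{vec.n_real_tokens} real tokens; indices 0/1 are reserved for "
      "padding and out-of-vocabulary words, real words start at 2")
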