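"""Parse ICD-9 codes and score them under the four match criteria.

A predicted code can be "right" at several granularities: same chapter,
same block, same three-digit category, or exactly the same full code.
"""

from notecode import MatchLevel, load_hierarchy, match_level, matches_at, parse_code

table = load_hierarchy()

predicted = parse_code("518.81", table)  # acute respiratory failure
actual = parse_code("518.82", table)     # other pulmonary insufficiency

print(f"predicted {predicted.full_code}: chapter {predicted.chapter_id}, "
      f"block {predicted.block_id}, category {predicted.category}")
print(f"actual    {actual.full_code}: chapter {actual.chapter_id}, "
      f"block {actual.block_id}, category {actual.category}")
for level in MatchLevel:
    print(f"  {level.display_name:<28} {'match' if matches_at(predicted, actual, level) else 'no match'}")
print(f"finest agreement: {match_level(predicted, actual).display_name}")
# The sibling subcategories agree everywhere except the full code, so a
# model predicting 518.81 for a true 518.82 is counted correct under the
# chapter, block, and category criteria but not the full-code one.

perinatal = parse_code("770.8", table)
print(f"\n770.8 vs 431 finest agreement: {match_level(perinatal, parse_code('431', table))}")
# None: a newborn respiratory condition and an intracerebral hemorrhage
# sit in different chapters, so the prediction is wrong at every level.
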