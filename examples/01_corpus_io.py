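"""Parse a standoff-annotated note, convert to BIO labels, and back.

Prints the parsed entity record, the BIO labels around the entity, and the
span recovered from the labels — all three agree exactly.
"""

from emrkg.corpus_io import bio_to_spans, parse_ann, spans_to_bio

text = "患者自述右肩背部隐痛两周，遂来院就诊。"
ann = ["T1\tsymptom 4 12\t右肩背部隐痛两周"]

doc = parse_ann(text, ann, doc_id="note001")
span = doc.spans[0]
print(f"parsed: id={span.span_id} type={span.entity_type} "
      f"offsets=[{span.start},{span.end}) surface={span.surface!r}")

(seq,) = spans_to_bio(doc)
print("BIO labels:", " ".join(seq.labels[4:13]), "...")

(recovered,) = bio_to_spans(seq)
print(f"recovered span: [{recovered.start},{recovered.end}) "
      f"type={recovered.entity_type} -> round-trip exact:",
      (recovered.start, recovered.end) == (span.start, span.end))
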