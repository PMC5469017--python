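# Co-occurrence pattern rules licensing a term-value link.
# rule_id,priority,slot_sequence,separator_class,max_gap,scope,value_kind,value_form,unit_mode
#
# slot_sequence  : space-separated slots over TERM / SEP / VALUE / UNIT
#                  (TERM_HEAD VALUE TERM_TAIL for the within-term variant)
# separator_class: equals | colon | column | verb | paren | adjacent
# value_form     : point | range
# unit_mode      : attached (unit inside the value mention) | detached
#                  (separate unit mention right after the value) | none | any
#
# Semi-structured, quantitative, one sequence per line
q01,10,TERM SEP VALUE,equals,40,LINE,QUANT,range,attached
q02,20,TERM SEP VALUE,equals,40,LINE,QUANT,point,attached
q03,30,TERM SEP VALUE UNIT,equals,40,LINE,QUANT,range,detached
q04,40,TERM SEP VALUE UNIT,equals,40,LINE,QUANT,point,detached
q05,50,TERM SEP VALUE,equals,40,LINE,QUANT,range,none
q06,60,TERM SEP VALUE,equals,40,LINE,QUANT,point,none
q07,70,TERM SEP VALUE,colon,40,LINE,QUANT,range,attached
q08,80,TERM SEP VALUE,colon,40,LINE,QUANT,point,attached
q09,90,TERM SEP VALUE UNIT,colon,40,LINE,QUANT,range,detached
q10,100,TERM SEP VALUE UNIT,colon,40,LINE,QUANT,point,detached
q11,110,TERM SEP VALUE,colon,40,LINE,QUANT,range,none
q12,120,TERM SEP VALUE,colon,40,LINE,QUANT,point,none
q13,130,TERM SEP VALUE,column,25,LINE,QUANT,range,attached
q14,140,TERM SEP VALUE,column,25,LINE,QUANT,point,attached
q15,150,TERM SEP VALUE UNIT,column,25,LINE,QUANT,range,detached
q16,160,TERM SEP VALUE UNIT,column,25,LINE,QUANT,point,detached
q17,170,TERM SEP VALUE,column,25,LINE,QUANT,range,none
q18,180,TERM SEP VALUE,column,25,LINE,QUANT,point,none
# Narrative, quantitative, verb-phrase separators within a sentence
n19,190,TERM SEP VALUE,verb,40,SENTENCE,QUANT,range,attached
n20,200,TERM SEP VALUE,verb,40,SENTENCE,QUANT,point,attached
n21,210,TERM SEP VALUE UNIT,verb,40,SENTENCE,QUANT,range,detached
n22,220,TERM SEP VALUE UNIT,verb,40,SENTENCE,QUANT,point,detached
n23,230,TERM SEP VALUE,verb,40,SENTENCE,QUANT,range,none
n24,240,TERM SEP VALUE,verb,40,SENTENCE,QUANT,point,none
# Parenthesized value directly after the term: "LVEF (55%)"
p25,250,TERM SEP VALUE,paren,10,LINE,QUANT,range,any
p26,260,TERM SEP VALUE,paren,10,LINE,QUANT,point,any
# Semi-structured qualitative: "Mitral regurgitation: mild"
s27,270,TERM SEP VALUE,equals,40,LINE,QUAL,range,none
s28,280,TERM SEP VALUE,equals,40,LINE,QUAL,point,none
s29,290,TERM SEP VALUE,colon,40,LINE,QUAL,range,none
s30,300,TERM SEP VALUE,colon,40,LINE,QUAL,point,none
# Narrative qualitative after a verb phrase: "aortic stenosis was mild"
n31,310,TERM SEP VALUE,verb,40,SENTENCE,QUAL,range,none
n32,320,TERM SEP VALUE,verb,40,SENTENCE,QUAL,point,none
# Qualitative inside the term: "aortic valve has mild stenosis"
w33,330,TERM_HEAD VALUE TERM_TAIL,within,20,SENTENCE,QUAL,range,none
w34,340,TERM_HEAD VALUE TERM_TAIL,within,20,SENTENCE,QUAL,point,none
# Qualitative before the term: "mild aortic stenosis"
v35,350,VALUE TERM,adjacent,5,SENTENCE,QUAL,range,none
v36,360,VALUE TERM,adjacent,5,SENTENCE,QUAL,point,none
# Bare whitespace column, qualitative: "Mitral regurgitation   mild"
s37,370,TERM SEP VALUE,column,25,LINE,QUAL,range,none
s38,380,TERM SEP VALUE,column,25,LINE,QUAL,point,none
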