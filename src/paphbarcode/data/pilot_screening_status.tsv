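voucher	species	ACO_F1/R1	ACO_F2/R2	LEAFY_F1/R1	LEAFY_F2/R2	ITS	matK	trnL	rpoB	rpoC1	trnH-psbA
DEL-2	Paphiopedilum delenatii	-/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/-
DEL-46	Paphiopedilum delenatii	-/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/-
DEL-47	Paphiopedilum delenatii					+/+	+/+	+/+	+/+	+/+	+/-
DEL-187	Paphiopedilum delenatii					+/+	+/+	+/+	+/+	+/+	+/-
DEL-188	Paphiopedilum delenatii					+/+	+/+	+/+	+/+	+/+	-/
DAL-138	Paphiopedilum x dalatense	-/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/+
DAL-139	Paphiopedilum x dalatense	-/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/+
DAL-143	Paphiopedilum x dalatense	-/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/-
GRA-145	Paphiopedilum gratrixianum	-/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/+
GRA-146	Paphiopedilum gratrixianum	-/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/-
GRA-180	Paphiopedilum gratrixianum					+/+	+/+	+/+	+/+	+/+	+/-
GRA-182	Paphiopedilum gratrixianum					+/+	+/+	+/+	+/+	+/+	+/-
HAN-16	Paphiopedilum hangianum	-/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/-
HAN-17	Paphiopedilum hangianum	+/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/-
HAN-18	Paphiopedilum hangianum	-/				+/+	+/+	+/+	+/+	+/+	+/-
HEL-69	Paphiopedilum helenae	-/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	-/
HEL-70	Paphiopedilum helenae	-/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/-
HEL-71	Paphiopedilum helenae					+/+	+/+	+/+	+/+	+/+	+/-
HER-177	Paphiopedilum x herrmannii					+/+	+/+	+/+	+/+	+/+	-/
TRA-63	Paphiopedilum tranlienianum	+/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/+
TRA-64	Paphiopedilum tranlienianum	+/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	+/+
TRA-66	Paphiopedilum tranlienianum	+/				+/+	+/+	+/+	+/+	+/+	+/+
VIE-130	Paphiopedilum vietnamense	+/	-/	-/	-/	+/+	+/+	+/+	+/+	+/+	-/
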