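product_id,oil_type,tomato_dose,yeast_product,yeast_dose,heat
soup01,corn,high,S99,low,short
soup02,corn,high,S99,high,long
soup03,olive,high,G28,low,short
soup04,olive,high,G28,high,long
soup05,corn,low,O31,low,short
soup06,corn,low,O31,high,long
soup07,olive,low,YPr,low,short
soup08,olive,low,YPr,high,long
soup09,olive,high,S99,low,long
soup10,corn,low,S99,high,short
soup11,corn,low,G28,low,long
soup12,olive,low,G28,high,short
soup13,olive,low,O31,low,long
soup14,corn,high,O31,high,short
soup15,corn,high,YPr,low,long
soup16,olive,high,YPr,high,short
soup17,olive,low,S99,low,short
soup18,olive,low,S99,high,long
soup19,corn,high,G28,low,short
soup20,corn,high,G28,high,long
soup21,olive,high,O31,low,short
soup22,olive,high,O31,high,long
soup23,corn,low,YPr,low,short
soup24,corn,low,YPr,high,long
soup25,corn,high,none,none,short
soup26,olive,low,none,none,long
soup27,olive,high,none,none,short
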