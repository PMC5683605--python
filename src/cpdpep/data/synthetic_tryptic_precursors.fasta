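;SYNTHETIC precursor scaffolds for the five-protein tryptic library.
;These are NOT database sequences.  Each scaffold is constructed so that
;tryptic digestion (cleavage after K/R, suppressed before P, up to two missed
;cleavages) yields every peptide attributed to that precursor in the packaged
;reference identification tables, in correct tryptic context.  The two
;hemoglobin entries carry the canonical mature human globin chain sequences;
;the other three are synthetic concatenations of reported tryptic peptides
;plus short filler segments.
>Thyroglobulin synthetic scaffold (bovine thyroglobulin stand-in)
QQAAALAKFPLGESFLAAKKGQEFTITGQKRKFEKLPESKSLSLKLTDEELAFPPLSPSR
KVVLQDRAVKQFEESQGRAFLGTVRFAATSFRAISVPEDIARASGLGAAAGQRGQEIPGT
RELSVLLPNRSALGEPKKGGSADE
>Bovine-serum-albumin synthetic scaffold (BSA stand-in)
ADLAKLVNELTEFAKLVTDLTKKQTALVELLKAEFVEVTKKVPQVSTPTLVEVSRIETMR
LVVSTQTALA
>alpha-Hemoglobin human hemoglobin alpha chain, mature sequence
VLSPADKTNVKAAWGKVGAHAGEYGAEALERMFLSFPTTKTYFPHFDLSHGSAQVKGHGK
KVADALTNAVAHVDDMPNALSALSDLHAHKLRVDPVNFKLLSHCLLVTLAAHLPAEFTPA
VHASLDKFLASVSTVLTSKYR
>beta-Hemoglobin human hemoglobin beta chain, mature sequence
VHLTPEEKSAVTALWGKVNVDEVGGEALGRLLVVYPWTQRFFESFGDLSTPDAVMGNPKV
KAHGKKVLGAFSDGLAHLDNLKGTFATLSELHCDKLHVDPENFRLLGNVLVCVLAHHFGK
EFTPPVQAAYQKVVAGVANALAHKYH
>alpha-Lactalbumin synthetic scaffold (bovine alpha-lactalbumin stand-in)
ELKDIPRANTVEGKSGFDPKLDQWLCEKALCSEKGGSA
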