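>p2seq05|AOI 1 orf003|Anaerotruncus colihominis DSM 17241
MEKPAVESIVKTAGNGTKRWYNRMKKQTAAITAVVCVFLFATHTQALEVPARVTRTVTTT
QKIPFATSYIDLPGIYRGYEEPVRSGTPGEQKIEAQVIYEGDRAVKVVSIKAEQTAQPVN
AVVKRGTKVLYSETADGSAWKTSFARPLKGGWLSADFYDYPHHNGIDLAAPYGTPVYAAA
EGVVEQAGWYGEYGICVILRHADGSRTLYGHNSSVSVSVGQTVKQGEKIANVGSTGNSTG
NHLHFEIRVDGRMIDPLVYLDQ
>p3seq17|AOI 1 smallORF 28|Bacteroides vulgatus PC510
MFHHSCLVMNIHIWECMSTTLAPQQQRVTLTVITGIVCFLSHTYQTTIRVLALSGTDSFT
NNGTTGISA
>p3seq16|AOI 1 smallORF 29|Bacteroides vulgatus PC510
MSTTLAPQQQRVTLTVITGIVCFLSHTYQTTIRVLALSGTDSFTNNGTTGISA
>p3seq24|AOI 1 orf007|Clostridium hathewayi DSM 13479
LEELIVNLVQSQGIWAVLFVFLLLYTIKKNDKLDELQEARERKYQELLTQLTVKLSIVNT
VNEKLDTIQAVLKEKSD
>p2seq14|AOI 1 smallORF 20|Clostridium nexile DSM 1787
MGLLEILPIIPYLLVRACDCTASDRTNTTYSCRRT
>p2seq08|AOI 1 orf006|Clostridium nexile DSM 1787
VERTFSLSKRCYGMSCITTKLEETQLTSIALSVFVTNLFRIQRRILCALLHLFRFWYDRN
RYKSWKLQIAA
>p2seq33|AOI 1 orf021|Clostridium nexile DSM 1787
MLKKKVKKYLLISGISFAIGTLGIIFVSVLIEEVVRAIAGEEANKQITQSDLEGLPAWIT
VEMVQAAIDMMNETGYPASVVLGQMILEAGADGSELANPPYYNCLGQKAHCYKENGTVVM
RTEEAWGTVTAEFSTFANYVDCMLAWGNKFTRQPYVDNVTACKRDPVTGHYDADSFITAL
WKSGYATDPAYVSKVIAVMKSRNLYRFNYMTSADLENGLGEIGTGMFTHPCPGMTYQSSY
FGEIREFETGGHKGNDYAAPAGTPTLAAADGTVTVAGWSDSAGNWVVIDHGNGLTTKYMH
HSRLLVKTGDTVKKGQQIGEVGSTGQSTGNHLHFQVEENGVPVNPDKYLKGEGNERE
>p2seq32|AOI 1 orf024|Clostridium nexile DSM 1787
MLRKKVKKYLLISGISFAIGILGIIFVSTLIEEVVRAIAGEEANKQIVQSDLDGLPAWIT
VEMVQAAIDMMNETGYPASVVLGQMILEAGADGSELANPPYYNCLGQKAHCYKESGTVVM
RTEEAWGTVTAEFSTFANYVDCMLAWGNKFTRQPYVDNVIACKRDPVTGHYDADSFITAL
WKSGYATDPAYVSKVIAVMKSRNLYRFNYMTSADLENGLGEIGNGMFTHPCPGMTYQSSY
FGEIREFETGGHKGNDYAAPAGTPTLAAADGIVTIAGWSDSAGNWVVIDHGNGLTTKYMH
HSKLLVKTGDTVKKGQQIGEVGSTGQSTGNHLHFQVEENGVPVNPDKYLKGDGE
>p2seq18|AOI 1 orf061|Clostridium nexile DSM 1787
VFTSFSLSSIATLPRLKEIILTSCFKHHFKEYTTLSISASPFLSNICILIISLSAKYFFI
IAAHIPPCIVVQLSRQKSKLFIMN
>p2seq20|AOI 2 smallORF 1|Clostridium nexile DSM 1787
MVAFVVISPITRTRPVLIATSHATRLSGSCLIHSSNTASAI
>p1seq09|AOI 1 smallORF 1|Dorea longicatena DSM 13814
MKRAATCHSHQHLTGLAERYAARHTSGSLQFLFFF
>p1seq16|AOI 1 orf012|Eubacterium ventriosum ATCC 27560
NKKSHKSAFVCIAVFMVTMIMILTFYQLAVEIYAYGFIAKNNDYRVKESTAKVLTLKENH
KAINIENINVNSKTKVINKKNINVNNFVLKKPVKGGITTSGFGDTISRTASHNGHDWAVN
TGTKVRAAAEGVVELAYFSESYGYNILINHNNGFKTRYAHLSEVKVSKGEKVEQSQVIAL
SGSTGFSTGPHLHFEVVKDGKRVNPIEYVSNR
>p3seq02|AOI 1 smallORF 15|Ruminococcus sp. 5.1.39.B FAA
MQVYSLFIFSASVYCKIITGKEDIRCSGTYN
>p3seq04|AOI 1 smallORF 20|Ruminococcus sp. 5.1.39.B FAA
MLNAAGCFRISFPTSDSDSLYSSFTVKTVAE
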