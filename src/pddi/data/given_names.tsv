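# given name lexicon: sex, kanji, reading (kana), optional alternative reading
# sex	kanji	kana	alt_kana
F	裕子	ゆうこ	ひろこ
F	陽子	ようこ	はるこ
F	幸子	さちこ	ゆきこ
F	恵子	けいこ	えこ
F	直美	なおみ
F	美香	みか
F	真由美	まゆみ
F	千春	ちはる
F	明美	あけみ
F	和子	かずこ
F	典子	のりこ
F	京子	きょうこ	けいこ
F	智子	ともこ	さとこ
F	由美	ゆみ	よしみ
F	愛	あい	めぐみ
F	綾	あや
F	香織	かおり
F	里奈	りな
F	美穂	みほ
F	彩花	あやか	さいか
F	優花	ゆうか
F	七海	ななみ
F	結衣	ゆい
F	桜	さくら
M	裕之	ひろゆき	やすゆき
M	健一	けんいち
M	直人	なおと	なおひと
M	大輔	だいすけ
M	翔太	しょうた
M	拓也	たくや
M	和彦	かずひこ
M	正人	まさと	まさひと
M	隆	たかし	りゅう
M	誠	まこと	せい
M	浩二	こうじ
M	雄大	ゆうだい	ゆうた
M	亮太	りょうた
M	智也	ともや
M	慎吾	しんご
M	大樹	だいき	ひろき
M	悠人	ゆうと	はると
M	陸	りく
M	蓮	れん
M	一郎	いちろう
M	修平	しゅうへい
M	康弘	やすひろ	みちひろ
M	哲也	てつや
M	昌幸	まさゆき
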