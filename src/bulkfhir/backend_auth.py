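"""SMART Backend Services authorization.

System-to-system trust with no human in the loop: a registered client signs
a short-lived assertion (a JWT) with its private key and posts it to the
token endpoint; the server verifies the signature against the registered
public key and issues a short-lived bearer access token carrying
``system/<ResourceType>.read`` scopes.  An optional per-client policy group
restricts every export that client performs to one group's patients
(e.g. a payor limited to its own plan members).

Wire format (token endpoint): HTTP POST, form-encoded, with
``grant_type=client_credentials``, ``scope``,
``client_assertion_type=urn:ietf:params:oauth:client-assertion-type:jwt-bearer``
and ``client_assertion``; success is a JSON object with ``access_token``,
``token_type``, ``expires_in`` and ``scope``.
"""
from __future__ import annotations

import re
import secrets
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Iterable, Mapping, Optional

from .fhir_core import SUPPORTED_RESOURCE_TYPES
from .rsa_jws import JwsError, RsaPrivateKey, RsaPublicKey, decode_jwt_unverified, sign_jwt, verify_jwt

__all__ = [
    "CLIENT_ASSERTION_TYPE",
    "ClientRegistration",
    "AccessToken",
    "AuthorizationDecision",
    "TokenRejection",
    "AuthorizationDenied",
    "AuthorizationServer",
    "build_client_assertion",
    "scope_covers",
]

CLIENT_ASSERTION_TYPE = "urn:ietf:params:oauth:client-assertion-type:jwt-bearer"

#: Maximum client-assertion lifetime and default access-token lifetime.
MAX_ASSERTION_LIFETIME = timedelta(minutes=5)
DEFAULT_TOKEN_LIFETIME = timedelta(seconds=300)

_SCOPE_RE = re.compile(r"^system/([A-Za-z]+|\*)\.read$")


def _now() -> datetime:
    return datetime.now(timezone.utc)


def parse_scope(scope: str) -> str:
    """Validate one scope string and return the resource type it grants."""
    m = _SCOPE_RE.match(scope)
    if not m:
        raise ValueError(f"malformed scope {scope!r}; expected system/<ResourceType>.read")
    rtype = m.group(1)
    if rtype != "*" and rtype not in SUPPORTED_RESOURCE_TYPES:
        raise ValueError(f"scope names unsupported resource type {rtype!r}")
    return rtype


def scope_covers(granted_scopes: Iterable[str], needed_types: Iterable[str]) -> bool:
    """True iff every needed type is readable under the granted scopes."""
    granted = {parse_scope(s) for s in granted_scopes}
    if "*" in granted:
        return True
    return set(needed_types) <= granted


@dataclass(frozen=True)
class ClientRegistration:
    """Pre-registered trust material for one backend client."""

    client_id: str
    public_key: RsaPublicKey
    allowed_scopes: frozenset[str]
    policy_group: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.client_id:
            raise ValueError("client_id must be nonempty")
        for scope in self.allowed_scopes:
            parse_scope(scope)


@dataclass(frozen=True)
class AccessToken:
    value: str
    granted_scopes: frozenset[str]
    expires_at: datetime

    def expires_in(self, now: datetime) -> int:
        return max(0, int((self.expires_at - now).total_seconds()))


@dataclass(frozen=True)
class AuthorizationDecision:
    client_id: str
    granted_types: frozenset[str]
    policy_group: Optional[str]


class TokenRejection(Exception):
    """Token-endpoint rejection with a distinguishable OAuth error code."""

    def __init__(self, error: str, description: str):
        super().__init__(f"{error}: {description}")
        self.error = error
        self.description = description


class AuthorizationDenied(Exception):
    """Denial on resource access.

    ``kind`` is ``"unauthenticated"`` (unknown/expired token; HTTP 401) or
    ``"forbidden"`` (valid token, insufficient scope; HTTP 403).
    """

    def __init__(self, kind: str, description: str):
        super().__init__(f"{kind}: {description}")
        self.kind = kind
        self.description = description


def build_client_assertion(
    client_id: str,
    signing_key: RsaPrivateKey,
    token_endpoint: str,
    now: Optional[datetime] = None,
    lifetime: timedelta = MAX_ASSERTION_LIFETIME,
    jti: Optional[str] = None,
) -> str:
    """Build the signed authentication JWT a client posts to the token endpoint.

    ``iss`` and ``sub`` both carry the client id; ``aud`` is the token
    endpoint URL; ``exp`` is ``now + lifetime`` (capped at five minutes);
    ``jti`` is a single-use identifier for replay protection.
    """
    if lifetime > MAX_ASSERTION_LIFETIME:
        raise ValueError("client assertion lifetime must not exceed 5 minutes")
    now = now or _now()
    claims = {
        "iss": client_id,
        "sub": client_id,
        "aud": token_endpoint,
        "exp": int((now + lifetime).timestamp()),
        "jti": jti or secrets.token_urlsafe(16),
    }
    return sign_jwt(claims, signing_key)


@dataclass
class _TokenRecord:
    client_id: str
    granted_scopes: frozenset[str]
    expires_at: datetime
    policy_group: Optional[str]


class AuthorizationServer:
    """Verifies client assertions, issues and checks bearer access tokens.

    Replay protection for assertion ``jti`` values is in-memory with
    expiry-bounded retention; token values are unguessable opaque strings
    mapped server-side to (client, scopes, expiry).
    """

    def __init__(
        self,
        token_endpoint: str,
        registrations: Iterable[ClientRegistration] = (),
        token_lifetime: timedelta = DEFAULT_TOKEN_LIFETIME,
    ):
        self.token_endpoint = token_endpoint
        self.token_lifetime = token_lifetime
        self._registry: dict[str, ClientRegistration] = {}
        for reg in registrations:
            self.register(reg)
        self._tokens: dict[str, _TokenRecord] = {}
        self._seen_jtis: dict[str, datetime] = {}

    def register(self, registration: ClientRegistration) -> None:
        if registration.client_id in self._registry:
            raise ValueError(f"duplicate client_id {registration.client_id!r}")
        self._registry[registration.client_id] = registration

    # -- token issuance ----------------------------------------------------

    def issue_token(
        self,
        assertion: str,
        requested_scopes: Iterable[str] | str,
        now: Optional[datetime] = None,
    ) -> AccessToken:
        """Exchange a signed client assertion for a short-lived access token.

        Grants ``requested ∩ allowed``; an empty intersection is rejected.
        Raises :class:`TokenRejection` with ``invalid_client`` (unknown
        client, bad signature, expired/malformed assertion),
        ``invalid_grant`` (replayed ``jti``), or ``invalid_scope``.
        """
        now = now or _now()
        if isinstance(requested_scopes, str):
            requested = frozenset(requested_scopes.split())
        else:
            requested = frozenset(requested_scopes)
        try:
            _, unverified = decode_jwt_unverified(assertion)
        except JwsError as exc:
            raise TokenRejection("invalid_client", f"malformed assertion: {exc}") from exc
        client_id = unverified.get("iss")
        registration = self._registry.get(client_id) if isinstance(client_id, str) else None
        if registration is None:
            raise TokenRejection("invalid_client", "unknown client")
        try:
            claims = verify_jwt(assertion, registration.public_key)
        except JwsError as exc:
            raise TokenRejection("invalid_client", f"assertion not verifiable: {exc}") from exc
        if claims.get("sub") != client_id:
            raise TokenRejection("invalid_client", "assertion iss and sub differ")
        if claims.get("aud") != self.token_endpoint:
            raise TokenRejection("invalid_client", "assertion audience mismatch")
        exp = claims.get("exp")
        if not isinstance(exp, (int, float)) or datetime.fromtimestamp(exp, timezone.utc) <= now:
            raise TokenRejection("invalid_client", "assertion expired")
        jti = claims.get("jti")
        if not isinstance(jti, str) or not jti:
            raise TokenRejection("invalid_client", "assertion lacks jti")
        self._prune_jtis(now)
        if jti in self._seen_jtis:
            raise TokenRejection("invalid_grant", "assertion replayed (jti already used)")
        self._seen_jtis[jti] = datetime.fromtimestamp(exp, timezone.utc)
        for scope in requested:
            try:
                parse_scope(scope)
            except ValueError as exc:
                raise TokenRejection("invalid_scope", str(exc)) from exc
        granted = requested & registration.allowed_scopes
        if not granted:
            raise TokenRejection("invalid_scope", "no requested scope is grantable")
        token = AccessToken(
            value=secrets.token_urlsafe(32),
            granted_scopes=granted,
            expires_at=now + self.token_lifetime,
        )
        self._tokens[token.value] = _TokenRecord(
            client_id=registration.client_id,
            granted_scopes=granted,
            expires_at=token.expires_at,
            policy_group=registration.policy_group,
        )
        return token

    def _prune_jtis(self, now: datetime) -> None:
        stale = [j for j, exp in self._seen_jtis.items() if exp <= now]
        for j in stale:
            del self._seen_jtis[j]

    def handle_token_request(
        self, form: Mapping[str, str], now: Optional[datetime] = None
    ) -> tuple[int, dict]:
        """Map a form-encoded token request to (HTTP status, JSON body)."""
        now = now or _now()
        if form.get("grant_type") != "client_credentials":
            return 400, {"error": "unsupported_grant_type",
                         "error_description": "grant_type must be client_credentials"}
        if form.get("client_assertion_type") != CLIENT_ASSERTION_TYPE:
            return 400, {"error": "invalid_request",
                         "error_description": "client_assertion_type must be the jwt-bearer URN"}
        assertion = form.get("client_assertion", "")
        scope = form.get("scope", "")
        try:
            token = self.issue_token(assertion, scope, now=now)
        except TokenRejection as exc:
            status = 401 if exc.error == "invalid_client" else 400
            return status, {"error": exc.error, "error_description": exc.description}
        return 200, {
            "access_token": token.value,
            "token_type": "bearer",
            "expires_in": token.expires_in(now),
            "scope": " ".join(sorted(token.granted_scopes)),
        }

    # -- request authorization --------------------------------------------

    def authorize(
        self,
        token_value: Optional[str],
        needed_types: Iterable[str],
        now: Optional[datetime] = None,
    ) -> AuthorizationDecision:
        """Check a bearer token against the resource types an export needs.

        A token is valid strictly before its ``expires_at``.  Raises
        :class:`AuthorizationDenied` — ``unauthenticated`` for missing,
        unknown or expired tokens, ``forbidden`` for insufficient scope.
        """
        now = now or _now()
        if not token_value:
            raise AuthorizationDenied("unauthenticated", "missing bearer token")
        record = self._tokens.get(token_value)
        if record is None:
            raise AuthorizationDenied("unauthenticated", "unknown token")
        if now >= record.expires_at:
            raise AuthorizationDenied("unauthenticated", "token expired")
        needed = frozenset(needed_types)
        if not scope_covers(record.granted_scopes, needed):
            granted = ", ".join(sorted(record.granted_scopes))
            raise AuthorizationDenied(
                "forbidden",
                f"granted scopes [{granted}] do not cover resource types {sorted(needed)}",
            )
        granted_types = frozenset(
            t for s in record.granted_scopes for t in (
                SUPPORTED_RESOURCE_TYPES if parse_scope(s) == "*" else {parse_scope(s)}
            )
        )
        return AuthorizationDecision(
            client_id=record.client_id,
            granted_types=granted_types,
            policy_group=record.policy_group,
        )
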